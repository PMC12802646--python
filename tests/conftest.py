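import numpy as np
import pytest

from snscore import (ModelConfig, SimConfig, load_core_panel, preprocess,
                     simulate_counts, train)
from snscore.scoring import score_cells


@pytest.fixture(scope="session")
def core_panel():
    return load_core_panel()


@pytest.fixture(scope="session")
def small_sim():
    """Small two-population dataset for unit tests (400 cells, 60 genes)."""
    cfg = SimConfig(n_cells=400, n_genes=60, seed=11)
    counts, truth = simulate_counts(cfg)
    return cfg, counts, truth


@pytest.fixture(scope="session")
def strong_run(core_panel):
    """One full pipeline run at strong, gene-heterogeneous effect sizes.

    Session-scoped because training dominates test runtime; tests that need
    a realistic fitted model and scores share this run.
    """
    cfg = SimConfig(seed=0, effect_log2fc=3.0, effect_log2fc_sd=1.0)
    counts, truth = simulate_counts(cfg)
    x_panel, processed = preprocess(counts, core_panel)
    fitted = train(
        x_panel.counts, processed.x_prime, processed.size_factors,
        ModelConfig(seed=0), panel_genes=processed.panel_genes,
    )
    result = score_cells(fitted, processed, seed=0)
    return {
        "config": cfg, "counts": counts, "truth": truth,
        "x_panel": x_panel, "processed": processed,
        "fitted": fitted, "result": result,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(123)
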