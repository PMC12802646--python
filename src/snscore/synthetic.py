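"""Synthetic data with the statistical structure the scoring model assumes.

The generator emulates the two-condition benchmark design used to validate
senescence scoring: zero-inflated negative-binomial counts with log-normal
baseline means and per-cell log-normal library-size variation, a senescent
subpopulation whose senescence-panel genes are shifted by a configured
log2 fold change (up for "induces" genes, down for "inhibits"), an optional
spatial grid with an injured region, and the targeted-panel (in situ style)
gene subsetting workflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .genesets import GeneSet, load_core_panel
from .preprocess import CountMatrix

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_counts",
    "simulate_spatial",
    "simulate_xenium_panel",
    "load_mock_base_panel",
]


@dataclass
class SimConfig:
    """Two-population ZINB simulation settings.

    Defaults mirror the desk-scale benchmark surface: 2,000 cells, 2,000
    genes including the 39-gene consensus panel, a 10% senescent population
    with a 1.5 log2 fold change on direction-labeled panel genes, moderate
    overdispersion (theta 2), 10% extra dropout, and 0.35-sd log-normal
    library-size variation.
    """

    n_cells: int = 2000
    n_genes: int = 2000
    panel: GeneSet = field(default_factory=load_core_panel)
    sen_fraction: float = 0.10
    effect_log2fc: float = 1.5
    effect_log2fc_sd: float = 0.0
    baseline_log_mean: float = 0.0
    baseline_log_sd: float = 1.0
    theta: float = 2.0
    dropout_pi: float = 0.10
    libsize_log_sd: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.sen_fraction < 1.0:
            raise ValueError("sen_fraction must lie in (0, 1)")
        if self.effect_log2fc < 0:
            raise ValueError("effect_log2fc must be non-negative")
        if self.effect_log2fc_sd < 0:
            raise ValueError("effect_log2fc_sd must be non-negative")
        if self.theta <= 0:
            raise ValueError("dispersion theta must be positive")
        if not 0.0 <= self.dropout_pi < 1.0:
            raise ValueError("dropout_pi must lie in [0, 1)")
        if self.n_genes < len(self.panel):
            raise ValueError("n_genes must be at least the panel size")


@dataclass
class SimTruth:
    """Ground-truth annotations accompanying a simulated matrix.

    ``base_means`` holds the per-gene baseline negative-binomial means
    actually drawn, and ``panel_effects`` the realized per-gene log2 fold
    changes, so tests can check the generator against its own targets.
    """

    labels: np.ndarray  # "senescent" / "normal" per cell
    region: np.ndarray | None = None  # "injured" / "healthy" per spot
    age_group: np.ndarray | None = None
    coordinates: np.ndarray | None = None  # spots x 2
    base_means: np.ndarray | None = None
    panel_effects: np.ndarray | None = None

    @property
    def is_senescent(self) -> np.ndarray:
        return self.labels == "senescent"


def _draw_zinb(rng, mean, theta, pi):
    """ZINB draw: NB(mean, dispersion) gamma-Poisson mixture + dropout."""
    lam = rng.gamma(shape=theta, scale=mean / theta)
    counts = rng.poisson(lam)
    drop = rng.random(counts.shape) < pi
    counts[drop] = 0
    return counts


def _simulate(config: SimConfig, sen_mask: np.ndarray,
              rng: np.random.Generator) -> tuple[CountMatrix, np.ndarray,
                                                 np.ndarray]:
    n, g = config.n_cells, config.n_genes
    panel_genes = list(config.panel.genes)
    gene_ids = panel_genes + [
        f"G{i:05d}" for i in range(1, g - len(panel_genes) + 1)
    ]
    base_mean = np.exp(rng.normal(
        config.baseline_log_mean, config.baseline_log_sd, size=g))
    lib_scale = np.exp(rng.normal(0.0, config.libsize_log_sd, size=n))

    mean = np.outer(lib_scale, base_mean)
    direction = config.panel.direction or {}
    # optional per-gene spread of the effect size: real senescence
    # signatures shift genes by very different fold changes, and gene-wise
    # heterogeneity is what the within-cell permutation null keys on
    effects = np.maximum(
        config.effect_log2fc
        + config.effect_log2fc_sd * rng.normal(size=len(panel_genes)),
        0.0,
    )
    for j, gene in enumerate(panel_genes):
        d = direction.get(gene, "induces")
        fold = 2.0 ** effects[j]
        if d == "induces":
            mean[sen_mask, j] *= fold
        elif d == "inhibits":
            mean[sen_mask, j] /= fold
        # "unknown" genes stay unshifted
    counts = _draw_zinb(rng, mean, config.theta, config.dropout_pi)
    cell_ids = np.array([f"cell{i:05d}" for i in range(1, n + 1)],
                        dtype=object)
    cm = CountMatrix(counts, cell_ids, np.array(gene_ids, dtype=object))
    return cm, base_mean, effects


def simulate_counts(config: SimConfig) -> tuple[CountMatrix, SimTruth]:
    """Two-population ZINB count matrix with a senescent subpopulation.

    The first ``round(sen_fraction * n_cells)`` cells (before a seeded
    shuffle) are senescent; panel genes labeled "induces" have their means
    multiplied by 2**effect_log2fc in those cells, "inhibits" genes divided.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cells
    n_sen = int(round(config.sen_fraction * n))
    sen_mask = np.zeros(n, dtype=bool)
    sen_mask[rng.permutation(n)[:n_sen]] = True
    counts, base_means, effects = _simulate(config, sen_mask, rng)
    labels = np.where(sen_mask, "senescent", "normal")
    return counts, SimTruth(labels=labels, base_means=base_means,
                            panel_effects=effects)


def simulate_spatial(
    config: SimConfig,
    grid: tuple[int, int] = (40, 50),
    injured_block: tuple[int, int, int, int] = (5, 5, 15, 20),
) -> tuple[CountMatrix, SimTruth]:
    """Spots on a rows x cols grid with an injured rectangular region.

    ``injured_block`` is (row0, col0, row1, col1), half-open; spots inside
    use the senescent expression profile.  The returned truth carries region
    labels and integer grid coordinates.
    """
    rows, cols = grid
    r0, c0, r1, c1 = injured_block
    if not (0 <= r0 <= r1 <= rows and 0 <= c0 <= c1 <= cols):
        raise ValueError("injured_block must lie inside the grid")
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    coords = np.column_stack([rr.ravel(), cc.ravel()])
    injured = (
        (coords[:, 0] >= r0) & (coords[:, 0] < r1)
        & (coords[:, 1] >= c0) & (coords[:, 1] < c1)
    )
    from dataclasses import replace

    cfg = replace(config, n_cells=rows * cols)
    rng = np.random.default_rng(cfg.seed)
    counts, base_means, effects = _simulate(cfg, injured, rng)
    truth = SimTruth(
        labels=np.where(injured, "senescent", "normal"),
        region=np.where(injured, "injured", "healthy"),
        coordinates=coords,
        base_means=base_means,
        panel_effects=effects,
    )
    return counts, truth


def simulate_xenium_panel(
    counts: CountMatrix,
    base_panel: list[str],
    sen_source: GeneSet,
    n_added: int,
    seed: int = 0,
) -> CountMatrix:
    """Targeted-panel reduction: base panel plus random senescence genes.

    Restricts the matrix to ``base_panel`` union ``n_added`` genes sampled
    without replacement (seeded) from ``sen_source`` minus the base panel,
    mimicking the expansion of a fixed commercial in-situ panel with
    senescence-associated probes.
    """
    base = {g.strip().upper() for g in base_panel}
    candidates = sorted(sen_source.as_set() - base)
    if n_added > len(candidates):
        raise ValueError(
            f"cannot add {n_added} genes; only {len(candidates)} senescence "
            "genes outside the base panel"
        )
    rng = np.random.default_rng(seed)
    added = set(rng.choice(candidates, size=n_added, replace=False)) \
        if n_added else set()
    keep_set = base | added
    mask = np.array([str(g).upper() in keep_set for g in counts.gene_ids])
    return counts.subset_genes(mask)


def load_mock_base_panel() -> list[str]:
    """The packaged 377-symbol mock multi-tissue base panel (synthetic)."""
    path = Path(resources.files("snscore") / "data"
                / "mock_xenium_base_panel.synthetic.tsv")
    with open(path) as fh:
        fh.readline()
        return [line.strip() for line in fh if line.strip()]
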