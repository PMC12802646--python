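# snscore

Senescence scoring for single-cell and spatial transcriptomics count data.

Senescent cells (SnCs) — cells in permanent cell-cycle arrest — are rare,
lack a single reliable marker gene, and published senescence gene sets
(SnGs) disagree heavily with one another.  `snscore` addresses this with
two pieces:

1. **A consensus senescence panel.**  Genes reported by at least five of
   nine senescence gene sets form a compact panel (39 genes, including
   canonical markers such as *CDKN1A*/p21 and *CDKN2A*/p16) that is far
   less sensitive to the inclusion bias of any single list.  The package
   ships synthetic stand-in gene sets for tests and examples and builds a
   consensus from any user-supplied GMT files.

2. **A decorrelated ZINB autoencoder.**  Panel counts x_ij are modeled as
   zero-inflated negative binomial,

       x_ij ~ pi_ij * delta_0 + (1 - pi_ij) * NB(mu_ij, theta_ij),

   with the NB parameterized by mean mu and dispersion theta.  The
   standardized log-normalized panel matrix X' is encoded through a 32-unit
   ReLU layer into a two-unit tanh bottleneck and decoded into three output
   heads (dropout pi, normalized mean mu', dispersion theta); the
   count-scale mean is mu = s_j * mu' with s_j the cell's size factor.  The
   objective is

       L = mean_ij [ -log ZINB(x_ij; pi_ij, mu_ij, theta_ij) ]
           + lambda * rho(h1, h2)^2,

   where h1, h2 are the bottleneck pre-activations and rho is their Pearson
   correlation (lambda = 1 by default).  The penalty forces the two latent
   units apart, so one specializes in the senescence signal.  After
   training, the unit most correlated with the panel genes — sign-anchored
   to *CDKN1A* expression — is the per-cell **senescence score**.  For a
   39-gene panel the whole network has 5,303 trainable parameters.

   Scores can be binarized: a within-cell gene-permutation null yields an
   uncertainty score per cell, a reliability cutoff is derived from it, and
   an AIC-selected 1-D Gaussian mixture turns scores into
   senescent / non-senescent calls.

The model is implemented in numpy (float64) with analytic gradients and a
full-batch Adam optimizer; gradients are verified against finite
differences in the test suite.

## Worked example

```bash
snscore simulate --n-cells 2000 --n-genes 2000 --seed 1 --outdir sim
snscore score sim/counts.csv --seed 1 --outdir scored
snscore evaluate scored/scores.tsv sim/truth.tsv --out eval.json
```

The `simulate` step writes a two-population ZINB count matrix (10%
senescent cells, 1.5 log2 fold change on the senescence panel) plus a truth
table.  `score` preprocesses, trains the autoencoder, and writes
`scores.tsv` (per-cell score, uncertainty, call) and a model checkpoint.
`evaluate` then prints:

```json
{
  "n_cells": 2000,
  "auroc": 0.9821,
  "accuracy": 0.957,
  "f1": 0.7528735632183908
}
```

The AUROC of 0.98 means a random senescent cell outscores a random normal
cell 98% of the time.  The binary calls are deliberately conservative —
here 148 of the 200 truly senescent cells are called (F1 0.75), the
permutation-ambiguous mid-scorers being left uncalled; with stronger,
gene-heterogeneous effects the calls recover the senescent population
almost exactly, and on weak-signal data the procedure can abstain entirely
(see `docs/methods.md`).

Library use mirrors the CLI:

```python
from snscore import (SimConfig, simulate_counts, preprocess, load_core_panel,
                     ModelConfig, train, auroc)
from snscore.scoring import score_cells

counts, truth = simulate_counts(SimConfig(seed=1))
x_panel, processed = preprocess(counts, load_core_panel())
fitted = train(x_panel.counts, processed.x_prime, processed.size_factors,
               ModelConfig(seed=1))
result = score_cells(fitted, processed, seed=1)
print(auroc(result.score, truth.is_senescent))
```

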