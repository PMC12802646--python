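# Methods

## Model

`snscore` scores cells for senescence with an autoencoder whose likelihood
matches the statistics of UMI counts.  For cell j and panel gene i the raw
count is modeled as zero-inflated negative binomial (ZINB): a point mass at
zero with probability pi_ij (technical dropout) mixed with a negative
binomial of mean mu_ij and dispersion theta_ij.  The encoder consumes X',
the denoised, library-size-normalized, log1p-transformed, panel-subsetted,
per-gene standardized expression matrix; the likelihood consumes the raw
panel counts X.  Size factors s_j (library size over median library size)
convert the decoder's normalized mean mu' to the count-scale mean
mu = s_j * mu', which makes the latent representation and the decoded
parameters independent of sequencing depth.

Architecture (all layers dense, with biases):

    E = ReLU(X' W_E + b_E)        32 units
    h = E W_B + b_B               2 units (pre-activation), B = tanh(h)
    D = ReLU(B W_D + b_D)         32 units
    Pi = sigmoid(D W_pi + b_pi)   dropout head
    M' = exp(D W_m + b_m)         mean head
    Theta = exp(D W_t + b_t)      dispersion head

Parameter count is 131·G + 194 for G input genes (5,303 at G = 39).

The objective is the mean entrywise ZINB negative log-likelihood plus
lambda · rho(h1, h2)^2, with rho the Pearson correlation of the two
bottleneck pre-activation vectors.  The penalty drives the two latent units
to carry uncorrelated information so that one unit can specialize in the
senescence signal while the other absorbs orthogonal variation.  The
default lambda = 1 reliably yields |rho| < 0.1 after training while leaving
the likelihood term dominant.

## Training

Full-batch Adam, learning rate 0.005, at most 300 epochs.  A seeded random
10% of cells is held out once before training; the validation metric is
the ZINB term alone on those cells (the penalty is excluded).  If the best
validation loss fails to improve (strict decrease, min_delta = 0) for 10
consecutive epochs the learning rate is halved; after 30 stagnant epochs
training stops.  The weights of the best validation epoch are restored.
Initialization is Glorot-uniform from a seeded generator; identical seeds
and data give bit-identical models.  Internal RNG streams (validation
split, permutation null) are salted so that a user seed shared with a data
generator cannot produce correlated draws — an unsalted split can otherwise
coincide exactly with a generator's subpopulation assignment.

Numerical guards: pi is clipped to [1e-8, 1 - 1e-8], the exp activations
are clamped to [1e-8, 1e8] (gradients masked where clamped), and all
arithmetic is float64.  The likelihood is evaluated in log space
(logaddexp for the zero case).  Analytic gradients of the full objective,
including the correlation penalty, are checked against central finite
differences to 1e-4 in the test suite.

## Scoring and binarization

The roles of the two bottleneck units are not identifiable during
training, so the senescence unit is chosen post hoc: for each unit, the
mean over panel genes of |Pearson(unit values, gene column of X')| is
computed and the larger mean wins (ties resolve to the lower index).  The
continuous score is that unit's pre-tanh value; the tanh-squashed value is
also exposed.  The sign is anchored to *CDKN1A* (p21) expression: a
negative correlation flips the score.  When the score–*CDKN1A* correlation
is smaller in magnitude than the two-sided 5% sampling bound 1.96/sqrt(n)
its sign carries no information, so orientation falls back to the mean of
the "induces"-labeled panel genes (flagged in the output); the same
fallback applies when *CDKN1A* is absent from the panel, as on small
targeted in-situ panels.

Binarization is two-step.  (1) Each cell's X' row is shuffled across panel
genes 50 times; each shuffled row is pushed through the fitted encoder and
the selected unit recorded.  The uncertainty score is the fraction of
permuted scores exceeding the observed score.  The score cutoff is the
smallest observed score value c such that fewer than 1% of cells scoring
above c have uncertainty above 0.5.  (2) A 1-D Gaussian mixture is fitted
to the scores for K = 2..10 components and the lowest-AIC K selected;
components whose 5% normal quantile (mean − 1.645·sd) exceeds the cutoff
are eligible, and cells assigned (maximum posterior) to the eligible
component with the smallest mean, or to any component with a larger mean,
are called senescent.  With no eligible component no cell is called.
Permuted scores reuse the fixed orientation; all strict inequalities are
implemented as stated.

The binarization is intentionally conservative and is all-or-nothing at
the component level: if a handful of mid-scoring cells remain
permutation-ambiguous, the cutoff rises and can disqualify every mixture
component, yielding zero calls even when the continuous score separates
the populations perfectly.  This is a property of the procedure, not a
defect of the fit; the continuous score is the primary output.

## Preprocessing

Optional QC retains cells with more than 200 and fewer than 7,000
expressed genes and under 20% mitochondrial counts (prefix `MT-` when
flags are absent); a prevalence filter keeps genes expressed in at least
1% of cells.  Denoising is pluggable: `identity` (default) or
`internal_zinb_ae`, a ZINB autoencoder over all genes (32-unit bottleneck,
no decorrelation penalty) whose estimated count-scale means, rounded to
integers, replace the raw counts.  Normalization scales each cell to the
median library size followed by natural log1p (equivalent to
`scanpy.pp.normalize_total` + `log1p` defaults, cross-checked in tests);
panel columns are standardized to zero mean and unit variance, with
zero-variance columns zeroed and flagged.

## Synthetic benchmark generator

`simulate_counts` emulates the two-condition benchmark design used to
validate senescence scoring: per-gene baseline means drawn log-normal
(mu = 0, sd = 1 on the log scale), per-cell library-size factors drawn
log-normal (sd 0.35), NB dispersion theta = 2, and 10% extra dropout —
together producing the overdispersed, sparse marginals typical of 10x
data.  A `sen_fraction` (default 10%) of cells is senescent: panel genes
labeled "induces" have their means multiplied by 2^effect_log2fc (default
1.5), "inhibits" genes divided by it.  `effect_log2fc_sd` (default 0)
optionally spreads the per-gene effect sizes, because real senescence
signatures shift genes by very different fold changes; gene-wise
heterogeneity is exactly what the within-cell permutation null keys on,
so homogeneous-effect data make the binarization (not the continuous
score) maximally conservative.  A spatial variant lays spots on a grid
with a rectangular "injured" block using the senescent profile, and a
targeted-panel helper restricts a matrix to a 377-gene mock base panel
plus randomly chosen senescence genes, mimicking in-situ panel expansion.

What the generator does not emulate: cell-type mixtures, batch effects,
spatial autocorrelation beyond the block design, gene–gene correlation
beyond the senescence program, and ambient RNA.  Passing tests on this
surface therefore demonstrate the mechanics of the method — depth
invariance, decorrelation, signal recovery at realistic noise — not
performance on any real tissue.

## Problem sizes and defaults

The benchmark surface is 2,000 cells × 2,000 genes (39 panel genes),
chosen as a desk-scale stand-in for the published two-condition
experiments; training the 5,303-parameter network on it takes a few
seconds.  Test fixtures use a few hundred cells.  The packaged nine gene
sets and the 39-gene consensus panel are synthetic stand-ins (see
`src/snscore/data/README.md`): they echo the size spread, the heavy
singleton tail, and the ≥5-of-9 consensus structure of the published
senescence-gene-set literature, with canonical marker symbols among the
consensus genes, but reproduce no published list.

## Known limitations

- Scores are not calibrated across datasets; only within-dataset ranking
  and calls are meaningful.
- Orientation depends on an anchor gene or direction labels; a panel with
  neither leaves the sign undefined (flagged, not guessed).
- The binarization can return zero calls on data with weak or homogeneous
  per-gene effects (see above).
- The internal denoiser is a convenience; on very small gene panels
  denoising is unnecessary and the identity option is the default.
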