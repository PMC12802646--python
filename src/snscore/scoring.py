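"""Continuous senescence score extraction, orientation, and binarization.

After fitting, one bottleneck unit carries the senescence signal and the
other nuisance variation; the roles are not identifiable during training, so
the senescence unit is picked post hoc as the one with the higher mean
absolute Pearson correlation with the panel genes in X'.  The sign is then
anchored so that the score correlates positively with CDKN1A (p21)
expression, the canonical senescence marker.

Binarization is two-step: a within-cell gene-permutation null gives each
cell an uncertainty score (the fraction of 50 permuted scores exceeding the
observed one); the score cutoff is the smallest value above which fewer than
1% of cells are unreliable (uncertainty > 0.5).  A 1-D Gaussian mixture
(K = 2..10, lowest AIC) is then fitted to the scores; components whose 5%
normal quantile clears the cutoff are eligible, and cells assigned to the
eligible component with the smallest mean — or to any component with a
larger mean — are called senescent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.mixture import GaussianMixture

from .model import FittedModel, pearson
from .preprocess import ProcessedMatrix

__all__ = [
    "ScoreResult",
    "identify_senescence_neuron",
    "orient_scores",
    "permutation_scores",
    "uncertainty",
    "score_cutoff",
    "gmm_binarize",
    "score_cells",
]

ANCHOR_GENE = "CDKN1A"
_Z05 = 1.6448536269514722  # standard normal 5% quantile magnitude


@dataclass
class MixtureSummary:
    """Diagnostics of the AIC-selected 1-D Gaussian mixture."""

    k: int
    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    aic_by_k: dict[int, float]
    assignments: np.ndarray
    senescent_components: list[int]


@dataclass
class ScoreResult:
    """Per-cell senescence scores and (optional) binary calls."""

    score: np.ndarray
    neuron_index: int
    orientation_flipped: bool
    orientation_anchor: str
    score_post_tanh: np.ndarray | None = None
    uncertainty: np.ndarray | None = None
    cutoff: float | None = None
    call: np.ndarray | None = None
    mixture: MixtureSummary | None = None
    cell_ids: np.ndarray | None = None
    neuron_mean_abs_corr: np.ndarray = field(
        default_factory=lambda: np.zeros(2))


def identify_senescence_neuron(
    model: FittedModel, x_prime: ProcessedMatrix | np.ndarray
) -> tuple[int, np.ndarray]:
    """Pick the bottleneck unit tracking the senescence panel.

    For each unit, the mean over panel genes of the absolute Pearson
    correlation between the unit's per-cell values and the gene's column of
    X' is computed; the unit with the larger mean wins (ties and constant
    units resolve to the lower index).
    """
    xp = x_prime.x_prime if isinstance(x_prime, ProcessedMatrix) else x_prime
    if xp.shape[1] < 2:
        raise ValueError("need at least 2 panel genes")
    h = model.encode(xp)
    mean_abs = np.zeros(h.shape[1])
    for k in range(h.shape[1]):
        if np.std(h[:, k]) < 1e-12:
            warnings.warn(
                f"bottleneck unit {k} is constant; correlations treated as 0",
                stacklevel=2,
            )
            continue
        corrs = [abs(pearson(h[:, k], xp[:, j])) for j in range(xp.shape[1])]
        mean_abs[k] = float(np.mean(corrs))
    return int(np.argmax(mean_abs)), mean_abs


def orient_scores(
    score: np.ndarray, anchor_expression: np.ndarray
) -> tuple[np.ndarray, bool]:
    """Flip the score sign if it anti-correlates with the anchor gene."""
    rho = pearson(score, anchor_expression)
    if rho < 0:
        return -score, True
    return score, False


def _anchor_column(
    processed: ProcessedMatrix, use_gene: bool = True
) -> tuple[np.ndarray | None, str]:
    genes = [str(g).upper() for g in processed.panel_genes]
    if use_gene and ANCHOR_GENE in genes:
        return processed.x_prime[:, genes.index(ANCHOR_GENE)], ANCHOR_GENE
    if processed.panel_direction:
        inducer_cols = [
            i for i, g in enumerate(genes)
            if processed.panel_direction.get(g) == "induces"
        ]
        if inducer_cols:
            return (processed.x_prime[:, inducer_cols].mean(axis=1),
                    "mean_induces")
    return None, "none"


def permutation_scores(
    model: FittedModel,
    x_prime: ProcessedMatrix | np.ndarray,
    neuron_index: int,
    n_perm: int = 50,
    seed: int = 0,
    flip: bool = False,
) -> np.ndarray:
    """Within-cell permutation null of the selected (oriented) unit.

    Each permutation independently shuffles every cell's X' row across the
    panel genes, pushes it through the already-fitted encoder, and records
    the selected unit's value.  Returns a cells x ``n_perm`` matrix.
    """
    xp = x_prime.x_prime if isinstance(x_prime, ProcessedMatrix) else x_prime
    rng = np.random.default_rng([seed, 0x9E37])  # salted stream
    n, g = xp.shape
    out = np.empty((n, n_perm))
    for p in range(n_perm):
        cols = np.argsort(rng.random((n, g)), axis=1)
        shuffled = np.take_along_axis(xp, cols, axis=1)
        h = model.encode(shuffled)
        out[:, p] = h[:, neuron_index]
    return -out if flip else out


def uncertainty(score: np.ndarray, permuted: np.ndarray) -> np.ndarray:
    """Fraction of permuted scores strictly exceeding each cell's score."""
    score = np.asarray(score, dtype=float)
    if permuted.shape[0] != score.shape[0]:
        raise ValueError("permuted matrix rows must match score length")
    return (permuted > score[:, None]).mean(axis=1)


def score_cutoff(
    score: np.ndarray,
    uncertainty: np.ndarray,
    max_unreliable_frac: float = 0.01,
    u_threshold: float = 0.5,
) -> float | None:
    """Smallest score value above which almost no cell is unreliable.

    Scans the sorted unique observed scores ascending and returns the
    smallest candidate c such that, among cells with score > c, the fraction
    with uncertainty > ``u_threshold`` is below ``max_unreliable_frac``;
    ``None`` when no candidate qualifies.
    """
    score = np.asarray(score, dtype=float)
    uncertainty = np.asarray(uncertainty, dtype=float)
    if score.size == 0:
        raise ValueError("empty score vector")
    if (uncertainty <= u_threshold).all():
        return float(score.min())  # condition holds at every candidate
    order = np.argsort(score, kind="stable")
    s_sorted = score[order]
    unreliable = (uncertainty[order] > u_threshold).astype(float)
    # suffix sums over cells strictly above each unique candidate
    candidates = np.unique(s_sorted)
    n_above = score.size - np.searchsorted(s_sorted, candidates, side="right")
    cum_unrel = np.concatenate([[0.0], np.cumsum(unreliable[::-1])])
    unrel_above = cum_unrel[n_above]
    ok = (n_above > 0) & (unrel_above / np.maximum(n_above, 1)
                          < max_unreliable_frac)
    if not ok.any():
        return None
    return float(candidates[np.argmax(ok)])


def gmm_binarize(
    score: np.ndarray,
    cutoff: float | None,
    k_range: tuple[int, int] = (2, 10),
    seed: int = 0,
) -> tuple[np.ndarray, MixtureSummary | None]:
    """AIC-selected Gaussian-mixture call of senescent vs non-senescent.

    Components whose 5% normal quantile (mean - 1.645 sd) exceeds the cutoff
    are eligible; cells assigned (max posterior) to the eligible component
    with the smallest mean, or any component with a larger mean, are called
    senescent.  With no cutoff or no eligible component every cell is
    non-senescent.
    """
    score = np.asarray(score, dtype=float)
    n = score.size
    calls = np.zeros(n, dtype=bool)
    if cutoff is None:
        return calls, None
    if np.std(score) < 1e-12:
        warnings.warn("degenerate (constant) scores; no senescent calls",
                      stacklevel=2)
        return calls, None
    if n < 20:
        raise ValueError("at least 20 cells are required for binarization")
    x = score.reshape(-1, 1)
    best = None
    aic_by_k: dict[int, float] = {}
    for k in range(k_range[0], k_range[1] + 1):
        if k >= n:
            break
        gm = GaussianMixture(n_components=k, random_state=seed)
        gm.fit(x)
        aic = gm.aic(x)
        aic_by_k[k] = float(aic)
        if best is None or aic < best[1]:
            best = (gm, aic, k)
    gm, _, k = best
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    assignments = gm.predict(x)
    eligible = np.where(means - _Z05 * sds > cutoff)[0]
    sen_components: list[int] = []
    if eligible.size:
        pivot_mean = means[eligible[np.argmin(means[eligible])]]
        sen_components = [int(c) for c in range(k) if means[c] >= pivot_mean]
        calls = np.isin(assignments, sen_components)
    summary = MixtureSummary(
        k=k, means=means, sds=sds, weights=gm.weights_.ravel(),
        aic_by_k=aic_by_k, assignments=assignments,
        senescent_components=sen_components,
    )
    return calls, summary


def score_cells(
    model: FittedModel,
    processed: ProcessedMatrix,
    binarize: bool = True,
    n_perm: int = 50,
    seed: int = 0,
) -> ScoreResult:
    """End-to-end scoring: select unit, orient, and optionally binarize."""
    neuron, mean_abs = identify_senescence_neuron(model, processed)
    h = model.encode(processed.x_prime)
    raw = h[:, neuron]
    anchor, anchor_name = _anchor_column(processed)
    if anchor is not None and anchor_name == ANCHOR_GENE:
        # a single noisy gene can produce a correlation whose sign is pure
        # sampling noise; below the two-sided 5% bound the anchor carries no
        # orientation information, so fall back to the panel-wide inducer
        # mean when direction labels allow it
        bound = 1.96 / np.sqrt(len(raw))
        if abs(pearson(raw, anchor)) < bound:
            fallback, fb_name = _anchor_column(processed, use_gene=False)
            if fallback is not None:
                warnings.warn(
                    "anchor-gene correlation not distinguishable from zero; "
                    "orienting on the mean of senescence-inducing panel "
                    "genes", stacklevel=2,
                )
                anchor, anchor_name = fallback, f"{fb_name}(weak_anchor)"
    if anchor is None:
        warnings.warn(
            "anchor gene absent and no direction labels available; "
            "scores returned unoriented", stacklevel=2,
        )
        oriented, flipped = raw, False
    else:
        oriented, flipped = orient_scores(raw, anchor)
    result = ScoreResult(
        score=oriented,
        neuron_index=neuron,
        orientation_flipped=flipped,
        orientation_anchor=anchor_name,
        score_post_tanh=np.tanh(oriented),
        cell_ids=processed.cell_ids,
        neuron_mean_abs_corr=mean_abs,
    )
    if binarize:
        permuted = permutation_scores(
            model, processed, neuron, n_perm=n_perm, seed=seed, flip=flipped
        )
        result.uncertainty = uncertainty(oriented, permuted)
        result.cutoff = score_cutoff(oriented, result.uncertainty)
        calls, mixture = gmm_binarize(oriented, result.cutoff, seed=seed)
        result.call = calls
        result.mixture = mixture
    return result
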