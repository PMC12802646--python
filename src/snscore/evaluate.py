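"""Evaluation statistics: AUROC, accuracy/F1, and age-group enrichment."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = ["BinaryConfusion", "auroc", "accuracy_f1", "snc_enrichment"]


@dataclass(frozen=True)
class BinaryConfusion:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @classmethod
    def from_calls(cls, predicted, truth) -> "BinaryConfusion":
        p = np.asarray(predicted, dtype=bool)
        t = np.asarray(truth, dtype=bool)
        return cls(
            tp=int((p & t).sum()), tn=int((~p & ~t).sum()),
            fp=int((p & ~t).sum()), fn=int((~p & t).sum()),
        )


def auroc(score, labels) -> float:
    """Probability a random positive outranks a random negative (ties 0.5).

    Computed from the rank-sum (Mann-Whitney) statistic, which is exact
    under ties, rather than by ROC-curve integration.
    """
    score = np.asarray(score, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute AUROC")
    ranks = rankdata(score)  # average ranks handle ties as 0.5 wins
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def accuracy_f1(confusion: BinaryConfusion) -> tuple[float, float]:
    """Accuracy (TP+TN)/total and F1 = 2PR/(P+R); 0/0 cases give 0 with a
    warning."""
    c = confusion
    total = c.tp + c.tn + c.fp + c.fn
    if total == 0:
        warnings.warn("empty confusion matrix; accuracy set to 0",
                      stacklevel=2)
        return 0.0, 0.0
    accuracy = (c.tp + c.tn) / total
    if c.tp + c.fp == 0 or c.tp + c.fn == 0 or c.tp == 0:
        if c.tp + c.fp == 0 or c.tp + c.fn == 0:
            warnings.warn("undefined precision or recall; F1 set to 0",
                          stacklevel=2)
        return accuracy, 0.0
    precision = c.tp / (c.tp + c.fp)
    recall = c.tp / (c.tp + c.fn)
    f1 = 2.0 * precision * recall / (precision + recall)
    return accuracy, f1


def snc_enrichment(score, group, top_frac: float = 0.01) -> float:
    """Old-vs-young enrichment among the top-scoring cells.

    The ``top_frac`` highest-scoring cells (a count, ties broken by stable
    cell order) form the top quantile; with a/b the old/young counts in the
    top quantile and c/d those below, the enrichment is
    (a/(a+b)) / (c/(c+d)).  Values above 1 mean senescence scores are
    enriched in the old group.
    """
    score = np.asarray(score, dtype=float)
    group = np.asarray(group)
    is_old = group == "old"
    is_young = group == "young"
    if not is_old.any() or not is_young.any():
        raise ValueError("both 'old' and 'young' groups must be present")
    n = score.size
    n_top = max(1, int(np.floor(top_frac * n)))
    # stable sort descending: negate scores, stable mergesort keeps input order
    order = np.argsort(-score, kind="stable")
    top = np.zeros(n, dtype=bool)
    top[order[:n_top]] = True
    a = int((top & is_old).sum())
    b = int((top & is_young).sum())
    c = int((~top & is_old).sum())
    d = int((~top & is_young).sum())
    if a + b == 0 or c + d == 0:
        raise ValueError("top or bottom quantile is empty")
    if c == 0:
        raise ValueError("no old-group cells below the top quantile; "
                         "enrichment undefined")
    return (a / (a + b)) / (c / (c + d))
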