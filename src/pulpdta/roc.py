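"""Empirical ROC curve, tie-aware Mann-Whitney AUC, bootstrap CI, Youden
threshold selection.

The AUC is computed as the Mann-Whitney probability that a random
reference-positive subject's marker exceeds a random negative's, with
ties counting 0.5 — which equals trapezoidal integration of the
empirical ROC exactly. Operating points are placed at every realized
marker value (inclusive >= positivity), not at midpoints, and the curve
always carries the (0,0) and (1,1) endpoints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import stats

from .cohort import Cohort, PatientRecord

__all__ = [
    "RocCurve",
    "empirical_roc",
    "auc_mann_whitney",
    "auc_trapezoidal",
    "auc_bootstrap_ci",
    "youden_optimal",
]


@dataclass(frozen=True)
class RocCurve:
    """Operating points ordered by decreasing threshold (increasing FPR)."""

    operating_points: tuple[tuple[float, float, float], ...]  # (thr, tpr, fpr)
    auc: float
    n_pos: int
    n_neg: int
    auc_ci: Optional[tuple[float, float]] = None

    @property
    def thresholds(self) -> np.ndarray:
        return np.array([p[0] for p in self.operating_points])

    @property
    def tpr(self) -> np.ndarray:
        return np.array([p[1] for p in self.operating_points])

    @property
    def fpr(self) -> np.ndarray:
        return np.array([p[2] for p in self.operating_points])


def _split_by_reference(
    cohort: Cohort,
    positive_rule: Optional[Callable[[PatientRecord], bool]],
) -> tuple[np.ndarray, np.ndarray]:
    labels = cohort.reference_labels(positive_rule)
    values = cohort.hs_crp
    pos, neg = values[labels], values[~labels]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("ROC requires at least one reference-positive and "
                         "one reference-negative subject")
    return pos, neg


def empirical_roc(
    cohort: Cohort,
    positive_rule: Optional[Callable[[PatientRecord], bool]] = None,
) -> RocCurve:
    """Empirical ROC with operating points at every distinct marker value.

    A sentinel threshold of +inf anchors (fpr, tpr) = (0, 0); the lowest
    realized value, where every subject tests positive, yields (1, 1).
    """
    pos, neg = _split_by_reference(cohort, positive_rule)
    values = np.concatenate([pos, neg])
    points = [(math.inf, 0.0, 0.0)]
    for thr in np.unique(values)[::-1]:
        tpr = float(np.mean(pos >= thr))
        fpr = float(np.mean(neg >= thr))
        points.append((float(thr), tpr, fpr))
    return RocCurve(
        operating_points=tuple(points),
        auc=auc_mann_whitney(pos, neg),
        n_pos=len(pos),
        n_neg=len(neg),
    )


def auc_mann_whitney(pos_values: Sequence[float],
                     neg_values: Sequence[float]) -> float:
    """P(pos > neg) + 0.5 P(pos = neg) over all pos x neg pairs.

    Computed via mid-ranks of the pooled sample (equivalent to the
    brute-force pairwise mean, and to trapezoidal integration of the
    empirical ROC).
    """
    pos = np.asarray(pos_values, dtype=float)
    neg = np.asarray(neg_values, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both groups must be non-empty")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    rank_sum_pos = ranks[:pos.size].sum()
    u = rank_sum_pos - pos.size * (pos.size + 1) / 2
    return float(u / (pos.size * neg.size))


def auc_trapezoidal(roc: RocCurve) -> float:
    """Trapezoidal area under the empirical curve (cross-check for the
    Mann-Whitney form; equal to machine precision)."""
    return float(np.trapezoid(roc.tpr, roc.fpr))


def auc_bootstrap_ci(
    cohort: Cohort,
    b: int = 10_000,
    confidence: float = 0.95,
    seed: int = 0,
    positive_rule: Optional[Callable[[PatientRecord], bool]] = None,
) -> tuple[float, float]:
    """Stratified percentile bootstrap interval for the AUC.

    Resampling is done with replacement within each reference class, so
    every resample keeps both classes (degenerate resamples cannot
    occur). Deterministic under a fixed seed.
    """
    if b < 100:
        raise ValueError("b must be >= 100")
    pos, neg = _split_by_reference(cohort, positive_rule)
    rng = np.random.default_rng(seed)
    n_pos, n_neg = len(pos), len(neg)
    aucs = np.empty(b)
    for i in range(b):
        p = pos[rng.integers(0, n_pos, n_pos)]
        q = neg[rng.integers(0, n_neg, n_neg)]
        aucs[i] = auc_mann_whitney(p, q)
    alpha = 1 - confidence
    lo, hi = np.quantile(aucs, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def youden_optimal(roc: RocCurve) -> tuple[float, float]:
    """Threshold maximizing Youden's J = tpr - fpr.

    Ties are broken toward the larger threshold (favoring specificity).
    The +inf sentinel point (J = 0) participates only if every realized
    point is negative, which cannot happen for a valid curve.
    """
    best_thr, best_j = math.inf, -math.inf
    # points are ordered by decreasing threshold: the first maximum wins,
    # which is the largest threshold among ties.
    for thr, tpr, fpr in roc.operating_points:
        j = tpr - fpr
        if j > best_j:
            best_thr, best_j = thr, j
    return float(best_thr), float(best_j)
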