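"""Tie-aware rank correlation with resampling inference, and normality
assessment.

Spearman's rho is the Pearson correlation of mid-ranks (average ranks
for ties) — the tie-aware form required here because the ordinal pain
categories guarantee heavy ties. Inference is by permutation (exact in
the limit, appropriate at n = 13), by exhaustive enumeration at tiny n,
or by the asymptotic t approximation; confidence intervals are
percentile bootstrap over subject pairs. Normality is assessed with the
Shapiro-Wilk test (Royston approximation via scipy), normal Q-Q series
using Blom-type (i - 0.375)/(n + 0.25) plotting positions, and a
Freedman-Diaconis histogram.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CorrelationResult",
    "NormalityResult",
    "BootstrapDegenerateError",
    "spearman_rho",
    "correlation_pvalue",
    "bootstrap_ci_statistic",
    "spearman_with_inference",
    "shapiro_wilk",
]


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    p_method: str  # {permutation, exhaustive, asymptotic}
    ci: tuple[float, float]
    b: int
    seed: int


@dataclass(frozen=True)
class NormalityResult:
    w_statistic: float
    p_value: float
    qq_points: tuple[tuple[float, float], ...]  # (theoretical, sample)
    histogram: tuple[tuple[tuple[float, float], int], ...]  # ((lo, hi), count)
    n: int


class BootstrapDegenerateError(RuntimeError):
    """Raised when the redraw cap for degenerate resamples is exceeded."""


def _ranks(v: np.ndarray) -> np.ndarray:
    return stats.rankdata(v)


def _check_xy(x: Sequence[float], y: Sequence[float]) -> tuple[np.ndarray,
                                                               np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    if x.size < 3:
        raise ValueError("need n >= 3")
    return x, y


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation of mid-ranks; NaN if either variable is constant."""
    x, y = _check_xy(x, y)
    rx, ry = _ranks(x), _ranks(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        return math.nan
    return float(np.dot(rx - rx.mean(), ry - ry.mean()) / (x.size * sx * sy))


def correlation_pvalue(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "permutation",
    b: int = 10_000,
    seed: int = 0,
) -> float:
    """Two-sided p-value for Spearman's rho.

    ``permutation``: proportion of |rho_perm| >= |rho_obs| over ``b``
    random permutations of y, with the add-one correction
    (1 + hits) / (1 + b). ``exhaustive``: enumerate all n! permutations
    (n <= 8) without the correction. ``asymptotic``: t approximation
    with n - 2 degrees of freedom.
    """
    x, y = _check_xy(x, y)
    rho_obs = spearman_rho(x, y)
    if math.isnan(rho_obs):
        raise ValueError("correlation undefined for constant input")
    n = x.size
    if method == "asymptotic":
        if abs(rho_obs) >= 1.0:
            return 0.0
        t = rho_obs * math.sqrt((n - 2) / (1 - rho_obs * rho_obs))
        return float(2 * stats.t.sf(abs(t), df=n - 2))
    rx = _ranks(x)
    ry = _ranks(y)
    cx = (rx - rx.mean()) / (rx.std() * n)
    cy = ry - ry.mean()
    sy = ry.std()
    if method == "exhaustive":
        if n > 8:
            raise ValueError("exhaustive enumeration limited to n <= 8")
        rhos = np.array([np.dot(cx, np.array(p)) / sy
                         for p in itertools.permutations(cy)])
        return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))
    if method != "permutation":
        raise ValueError(f"unknown p-value method {method!r}")
    rng = np.random.default_rng(seed)
    # vectorized: permuting y then ranking == permuting y's mid-ranks
    perms = np.empty((b, n))
    for i in range(b):
        perms[i] = rng.permutation(cy)
    rhos = perms @ cx / sy
    hits = int(np.sum(np.abs(rhos) >= abs(rho_obs) - 1e-12))
    return (1 + hits) / (1 + b)


def bootstrap_ci_statistic(
    pairs: Sequence[tuple[float, float]],
    statistic: Callable[[np.ndarray, np.ndarray], float],
    b: int = 10_000,
    confidence: float = 0.95,
    seed: int = 0,
    max_redraws_per_resample: int = 100,
) -> tuple[float, float]:
    """Percentile bootstrap interval for a paired-sample statistic.

    Subject pairs are resampled with replacement; resamples where the
    statistic is undefined (NaN, e.g. a constant variable) are redrawn,
    capped at ``max_redraws_per_resample`` consecutive failures, beyond
    which :class:`BootstrapDegenerateError` is raised.
    """
    if b < 100:
        raise ValueError("b must be >= 100")
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be a sequence of (x, y) tuples")
    n = arr.shape[0]
    rng = np.random.default_rng(seed)
    out = np.empty(b)
    for i in range(b):
        for attempt in range(max_redraws_per_resample + 1):
            idx = rng.integers(0, n, n)
            value = statistic(arr[idx, 0], arr[idx, 1])
            if not math.isnan(value):
                out[i] = value
                break
        else:
            raise BootstrapDegenerateError(
                f"statistic undefined in {max_redraws_per_resample} "
                f"consecutive resamples")
    alpha = 1 - confidence
    lo, hi = np.quantile(out, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def spearman_with_inference(
    x: Sequence[float],
    y: Sequence[float],
    p_method: str = "permutation",
    b: int = 10_000,
    confidence: float = 0.95,
    seed: int = 0,
) -> CorrelationResult:
    """Convenience bundle: rho, p-value, and percentile-bootstrap CI."""
    x, y = _check_xy(x, y)
    rho = spearman_rho(x, y)
    p = correlation_pvalue(x, y, method=p_method, b=b, seed=seed)
    ci = bootstrap_ci_statistic(
        np.column_stack([x, y]), spearman_rho, b=b,
        confidence=confidence, seed=seed + 1)
    return CorrelationResult(rho=rho, p_value=p, p_method=p_method,
                             ci=ci, b=b, seed=seed)


def shapiro_wilk(values: Sequence[float]) -> NormalityResult:
    """Shapiro-Wilk W and p, normal Q-Q series, and an FD histogram.

    Valid for 3 <= n <= 5000. Constant input yields W = NaN (the
    statistic is undefined). Q-Q plotting positions are
    (i - 0.375)/(n + 0.25); the histogram bin count follows the
    Freedman-Diaconis rule (numpy ``bins="fd"``).
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or not 3 <= v.size <= 5000:
        raise ValueError("need a 1-D sample with 3 <= n <= 5000")
    n = v.size
    srt = np.sort(v)
    positions = (np.arange(1, n + 1) - 0.375) / (n + 0.25)
    theo = stats.norm.ppf(positions)
    qq = tuple((float(t), float(s)) for t, s in zip(theo, srt))
    if np.ptp(v) == 0:
        w, p = math.nan, math.nan
        counts, edges = np.histogram(v, bins=1)
    else:
        w, p = stats.shapiro(v)
        counts, edges = np.histogram(v, bins="fd")
    hist = tuple(((float(edges[i]), float(edges[i + 1])), int(counts[i]))
                 for i in range(len(counts)))
    return NormalityResult(
        w_statistic=float(w), p_value=float(p), qq_points=qq,
        histogram=hist, n=n)
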