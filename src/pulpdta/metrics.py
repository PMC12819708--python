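"""Threshold classification and 2x2 diagnostic accuracy metrics.

Implements the classical diagnostic-accuracy toolkit for a continuous
biomarker dichotomized at a threshold against a binarized clinical
reference: confusion tables, sensitivity/specificity/PPV/NPV with Wilson
score or Clopper-Pearson exact binomial intervals, likelihood ratios
with log-method confidence intervals, odds-form Bayesian post-test
probabilities, and the multi-threshold report.

Test positivity is inclusive: marker >= threshold is positive, so ties
at the threshold count as positive. The default reference predicate is
"severe pain", i.e. ordinal pain category >= 3.

Degenerate tables (no reference positives or no reference negatives)
degrade gracefully: the affected proportions come back undefined
(``None``) and likelihood ratios may carry an infinite or undefined
flag, but no exception is raised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import stats

from .cohort import Cohort, PatientRecord

__all__ = [
    "ConfusionTable",
    "ProportionCI",
    "LikelihoodRatio",
    "MetricSet",
    "classify_at_threshold",
    "proportion_metrics",
    "wilson_interval",
    "clopper_pearson_interval",
    "likelihood_ratios",
    "posttest_probability",
    "threshold_report",
]


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 counts of an index test against a binary reference."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, "
                                 f"got {v!r}")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_pos(self) -> int:
        """Reference-positive count."""
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        """Reference-negative count."""
        return self.fp + self.tn

    @property
    def degenerate(self) -> bool:
        """True when only one reference class is present."""
        return self.n_pos == 0 or self.n_neg == 0

    @property
    def prevalence(self) -> float:
        return self.n_pos / self.n


@dataclass(frozen=True)
class ProportionCI:
    estimate: float
    lower: float
    upper: float
    method: str  # {wilson, clopper_pearson}
    confidence: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.lower <= self.estimate <= self.upper <= 1.0):
            raise ValueError(
                f"interval must satisfy 0 <= lower <= estimate <= upper <= 1, "
                f"got ({self.lower}, {self.estimate}, {self.upper})")


@dataclass(frozen=True)
class LikelihoodRatio:
    """LR point estimate with a log-method CI.

    ``value`` may be ``inf`` (zero-cell denominator under the exact
    policy) or ``nan`` (0/0); ``finite`` records whether the estimate is
    a finite number. The CI is ``None`` whenever the log-method standard
    error is undefined (any relevant zero cell under the exact policy).
    """

    value: float
    lower: Optional[float]
    upper: Optional[float]
    policy: str  # {exact, haldane}

    @property
    def finite(self) -> bool:
        return math.isfinite(self.value)

    @property
    def defined(self) -> bool:
        return not math.isnan(self.value)


@dataclass(frozen=True)
class MetricSet:
    """All accuracy metrics at one threshold.

    ``posttest_pos`` equals the PPV estimate exactly whenever the
    pretest probability is the sample prevalence (Bayes consistency).
    Undefined proportions (zero denominator) are ``None``.
    """

    threshold: float
    sensitivity: Optional[ProportionCI]
    specificity: Optional[ProportionCI]
    ppv: Optional[ProportionCI]
    npv: Optional[ProportionCI]
    lr_pos: LikelihoodRatio
    lr_neg: LikelihoodRatio
    pretest: float
    posttest_pos: Optional[float]
    posttest_neg: Optional[float]
    table: ConfusionTable
    degenerate: bool


def classify_at_threshold(
    cohort: Cohort,
    threshold: float,
    positive_rule: Optional[Callable[[PatientRecord], bool]] = None,
) -> ConfusionTable:
    """Cross-classify marker >= threshold against the reference predicate."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    test_pos = cohort.hs_crp >= threshold
    ref_pos = cohort.reference_labels(positive_rule)
    return ConfusionTable(
        tp=int(np.sum(test_pos & ref_pos)),
        fp=int(np.sum(test_pos & ~ref_pos)),
        fn=int(np.sum(~test_pos & ref_pos)),
        tn=int(np.sum(~test_pos & ~ref_pos)),
    )


def wilson_interval(successes: int, trials: int,
                    confidence: float = 0.95) -> ProportionCI:
    """Wilson score interval (closed form, inverts the score test).

    Satisfies the complement symmetry
    ``wilson(k, n) = 1 - reversed wilson(n - k, n)``. For k = n the
    lower bound is n / (n + z^2).
    """
    _check_counts(successes, trials, confidence)
    z = stats.norm.ppf(1 - (1 - confidence) / 2)
    p = successes / trials
    z2n = z * z / trials
    denom = 1 + z2n
    center = p + z2n / 2
    half = z * math.sqrt(p * (1 - p) / trials + z * z / (4 * trials * trials))
    # at k = 0 / k = n the score bounds are exactly 0 / 1; the closed
    # form only reaches them up to floating-point round-off
    lower = 0.0 if successes == 0 else max(0.0, (center - half) / denom)
    upper = 1.0 if successes == trials else min(1.0, (center + half) / denom)
    return ProportionCI(
        estimate=p,
        lower=float(lower),
        upper=float(upper),
        method="wilson",
        confidence=confidence,
    )


def clopper_pearson_interval(successes: int, trials: int,
                             confidence: float = 0.95) -> ProportionCI:
    """Exact binomial interval by inverting the binomial tails
    (beta quantiles). k = n gives upper = 1; k = 0 gives lower = 0."""
    _check_counts(successes, trials, confidence)
    alpha = 1 - confidence
    if successes == 0:
        lower = 0.0
    else:
        lower = float(stats.beta.ppf(alpha / 2, successes,
                                     trials - successes + 1))
    if successes == trials:
        upper = 1.0
    else:
        upper = float(stats.beta.ppf(1 - alpha / 2, successes + 1,
                                     trials - successes))
    return ProportionCI(
        estimate=successes / trials,
        lower=lower,
        upper=upper,
        method="clopper_pearson",
        confidence=confidence,
    )


def _check_counts(successes: int, trials: int, confidence: float) -> None:
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if not 0 <= successes <= trials:
        raise ValueError("successes must lie in [0, trials]")
    if not 0 < confidence < 1:
        raise ValueError("confidence must lie in (0, 1)")


_INTERVALS = {
    "wilson": wilson_interval,
    "clopper_pearson": clopper_pearson_interval,
}


def proportion_metrics(
    ct: ConfusionTable,
    method: str = "wilson",
    confidence: float = 0.95,
) -> dict[str, Optional[ProportionCI]]:
    """Se, Sp, PPV, NPV with the requested binomial interval.

    A zero denominator makes that single proportion ``None``; the
    others are unaffected.
    """
    if method not in _INTERVALS:
        raise ValueError(f"unknown interval method {method!r}")
    interval = _INTERVALS[method]

    def prop(k: int, n: int) -> Optional[ProportionCI]:
        return interval(k, n, confidence) if n > 0 else None

    return {
        "sensitivity": prop(ct.tp, ct.tp + ct.fn),
        "specificity": prop(ct.tn, ct.tn + ct.fp),
        "ppv": prop(ct.tp, ct.tp + ct.fp),
        "npv": prop(ct.tn, ct.tn + ct.fn),
    }


def likelihood_ratios(
    ct: ConfusionTable,
    zero_cell_policy: str = "exact",
    confidence: float = 0.95,
) -> tuple[LikelihoodRatio, LikelihoodRatio]:
    """LR+ = Se/(1-Sp) and LR- = (1-Se)/Sp with log-method CIs.

    The log-method SE for LR+ is
    sqrt(1/tp - 1/(tp+fn) + 1/fp - 1/(fp+tn)); analogously for LR-
    with fn and tn. Under the ``haldane`` policy 0.5 is added to every
    cell before anything is computed. Under the ``exact`` policy a zero
    denominator cell yields an infinite LR flag (not an exception), a
    zero numerator yields LR = 0 exactly with an undefined CI, and 0/0
    yields NaN.
    """
    if zero_cell_policy not in {"exact", "haldane"}:
        raise ValueError(f"unknown zero_cell_policy {zero_cell_policy!r}")
    if zero_cell_policy == "haldane":
        tp, fp, fn, tn = (ct.tp + 0.5, ct.fp + 0.5, ct.fn + 0.5, ct.tn + 0.5)
    else:
        tp, fp, fn, tn = float(ct.tp), float(ct.fp), float(ct.fn), float(ct.tn)
    z = stats.norm.ppf(1 - (1 - confidence) / 2)

    lr_pos = _one_lr(num=tp, num_tot=tp + fn, den=fp, den_tot=fp + tn,
                     z=z, policy=zero_cell_policy)
    lr_neg = _one_lr(num=fn, num_tot=tp + fn, den=tn, den_tot=fp + tn,
                     z=z, policy=zero_cell_policy)
    return lr_pos, lr_neg


def _one_lr(num: float, num_tot: float, den: float, den_tot: float,
            z: float, policy: str) -> LikelihoodRatio:
    # LR = (num/num_tot) / (den/den_tot); for LR+ num=tp, den=fp.
    if num_tot == 0 or den_tot == 0:
        return LikelihoodRatio(math.nan, None, None, policy)
    if den == 0:
        value = math.inf if num > 0 else math.nan
        return LikelihoodRatio(value, None, None, policy)
    value = (num / num_tot) / (den / den_tot)
    if num == 0:
        return LikelihoodRatio(0.0, None, None, policy)
    se = math.sqrt(1 / num - 1 / num_tot + 1 / den - 1 / den_tot)
    log_lr = math.log(value)
    return LikelihoodRatio(
        value=value,
        lower=math.exp(log_lr - z * se),
        upper=math.exp(log_lr + z * se),
        policy=policy,
    )


def posttest_probability(pretest: float, lr: float) -> float:
    """Odds-form Bayes update: posterior odds = pretest odds * LR.

    Equals the PPV exactly when ``pretest`` is the sample prevalence and
    ``lr`` the sample LR+. An infinite LR gives probability 1.
    """
    if not 0 < pretest < 1:
        raise ValueError("pretest probability must lie strictly in (0, 1)")
    if lr < 0:
        raise ValueError("likelihood ratio must be >= 0")
    if math.isinf(lr):
        return 1.0
    return pretest * lr / (pretest * lr + 1 - pretest)


def threshold_report(
    cohort: Cohort,
    thresholds: Sequence[float],
    ci_method: str = "wilson",
    confidence: float = 0.95,
    zero_cell_policy: str = "exact",
    positive_rule: Optional[Callable[[PatientRecord], bool]] = None,
    pretest: Optional[float] = None,
) -> list[MetricSet]:
    """One :class:`MetricSet` per threshold, in input order.

    ``pretest`` defaults to the sample prevalence of the reference
    condition, which makes the post-test probabilities Bayes-consistent
    with PPV and 1 - NPV.
    """
    if len(thresholds) == 0:
        raise ValueError("thresholds must be non-empty")
    out = []
    for thr in thresholds:
        ct = classify_at_threshold(cohort, thr, positive_rule)
        props = proportion_metrics(ct, ci_method, confidence)
        lr_pos, lr_neg = likelihood_ratios(ct, zero_cell_policy, confidence)
        pre = ct.prevalence if pretest is None else pretest
        post_pos = post_neg = None
        if 0 < pre < 1:
            if lr_pos.defined:
                post_pos = posttest_probability(pre, lr_pos.value)
            if lr_neg.defined:
                post_neg = posttest_probability(pre, lr_neg.value)
        out.append(MetricSet(
            threshold=float(thr),
            sensitivity=props["sensitivity"],
            specificity=props["specificity"],
            ppv=props["ppv"],
            npv=props["npv"],
            lr_pos=lr_pos,
            lr_neg=lr_neg,
            pretest=pre,
            posttest_pos=post_pos,
            posttest_neg=post_neg,
            table=ct,
            degenerate=ct.degenerate,
        ))
    return out
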