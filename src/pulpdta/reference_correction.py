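"""Monte Carlo correction of apparent accuracy for an imperfect reference.

When the clinical reference standard itself misclassifies (here, ordinal
pain assessment used as the truth for "severe" disease), the apparent
sensitivity and specificity of the index test are biased. Two explicit
correction models are provided, and every output records which one was
used — the choice is material and no silent default interpretation is
made:

``algebraic_inversion``
    Assume the reference has known (se_r, sp_r) and that index and
    reference errors are conditionally independent given the true state.
    With q the observed reference-positive rate, the true prevalence is
    pi = (q + sp_r - 1) / (se_r + sp_r - 1), and the observed joint
    rates P(T+, R+) and P(T+, R-) form a linear system in
    (pi*se_t, (1-pi)*(1-sp_t)) whose solution recovers the index test's
    true sensitivity and specificity. At small n the solution can fall
    outside [0, 1] (a known behavior of misclassification inversion);
    such draws are discarded and counted by default, or clamped under
    the ``clip`` policy.

``label_perturbation``
    Treat the observed labels as noisy: flip each observed positive with
    probability 1 - se_r and each observed negative with probability
    1 - sp_r, then recompute the index test's Se/Sp against the
    perturbed labels.

The Monte Carlo layer draws (se_r, sp_r) uniformly and independently
over stated plausibility ranges (the source material states ranges
only), runs the chosen model per draw, and summarizes valid draws by
median and quartiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .cohort import Cohort
from .metrics import ConfusionTable, classify_at_threshold

__all__ = [
    "ReferenceAssumption",
    "CorrectedDraw",
    "CorrectionSummary",
    "sample_reference_performance",
    "invert_joint_rates",
    "invert_misclassification",
    "perturb_labels_correction",
    "monte_carlo_correction",
]


@dataclass(frozen=True)
class ReferenceAssumption:
    """Plausibility ranges for the true reference performance plus the
    Monte Carlo settings. Defaults follow published ranges for clinical
    pain assessment: sensitivity 75-90%, specificity 60-80%, 10,000
    iterations."""

    se_range: tuple[float, float] = (0.75, 0.90)
    sp_range: tuple[float, float] = (0.60, 0.80)
    n_iterations: int = 10_000
    model: str = "algebraic_inversion"  # or "label_perturbation"
    invalid_policy: str = "discard"     # or "clip"
    seed: int = 0

    def __post_init__(self) -> None:
        for name, (lo, hi) in (("se_range", self.se_range),
                               ("sp_range", self.sp_range)):
            if not 0 < lo <= hi <= 1:
                raise ValueError(f"{name} must satisfy 0 < low <= high <= 1")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.model not in {"algebraic_inversion", "label_perturbation"}:
            raise ValueError(f"unknown model {self.model!r}")
        if self.invalid_policy not in {"discard", "clip"}:
            raise ValueError(f"unknown invalid_policy {self.invalid_policy!r}")


@dataclass(frozen=True)
class CorrectedDraw:
    se_t: float
    sp_t: float
    prevalence: Optional[float]
    valid: bool
    clipped: bool = False


@dataclass(frozen=True)
class CorrectionSummary:
    """Median/quartile summaries of the corrected Se/Sp over valid draws."""

    model: str
    corrected_se: tuple[float, float, float]  # (median, q1, q3)
    corrected_sp: tuple[float, float, float]
    n_valid: int
    n_invalid: int
    n_iterations: int
    invalid_policy: str
    draws: Optional[np.ndarray] = None  # columns: se_r, sp_r, se_t, sp_t, valid

    @property
    def empty(self) -> bool:
        return self.n_valid == 0


def sample_reference_performance(
    assumption: ReferenceAssumption,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Draw (se_r, sp_r) pairs: independent uniforms on each stated range.

    Returns an (n_iterations, 2) array; deterministic under the
    assumption's seed when no generator is supplied.
    """
    rng = rng if rng is not None else np.random.default_rng(assumption.seed)
    se = rng.uniform(*assumption.se_range, size=assumption.n_iterations)
    sp = rng.uniform(*assumption.sp_range, size=assumption.n_iterations)
    return np.column_stack([se, sp])


def invert_joint_rates(
    p_tpos_rpos: float,
    p_tpos_rneg: float,
    q: float,
    se_r: float,
    sp_r: float,
) -> tuple[float, float, float]:
    """Solve the conditional-independence system for (se_t, sp_t, pi).

    Inputs are the observed joint rates a = P(test+, ref+) and
    b = P(test+, ref-), the observed reference-positive rate q, and the
    assumed reference performance. Raw (unclamped) solutions are
    returned; callers decide the invalid-draw policy. Requires
    se_r + sp_r > 1 (reference better than chance).
    """
    d = se_r + sp_r - 1.0
    if d <= 0:
        raise ValueError("need se_r + sp_r > 1 (reference better than chance)")
    pi = (q + sp_r - 1.0) / d
    # a = x*se_r + y*(1-sp_r);  b = x*(1-se_r) + y*sp_r
    # with x = pi*se_t, y = (1-pi)*(1-sp_t); determinant = d.
    x = (p_tpos_rpos * sp_r - p_tpos_rneg * (1.0 - sp_r)) / d
    y = (p_tpos_rneg * se_r - p_tpos_rpos * (1.0 - se_r)) / d
    se_t = x / pi if pi != 0 else math.nan
    sp_t = 1.0 - y / (1.0 - pi) if pi != 1 else math.nan
    return float(se_t), float(sp_t), float(pi)


def invert_misclassification(
    ct: ConfusionTable,
    se_r: float,
    sp_r: float,
    invalid_policy: str = "discard",
) -> CorrectedDraw:
    """Algebraic correction of one 2x2 table for one (se_r, sp_r) draw.

    With a perfect reference (se_r = sp_r = 1) the corrected values
    equal the observed Se/Sp exactly and pi equals the observed
    reference-positive rate. Out-of-range solutions are flagged invalid
    (``discard``) or clamped to [0, 1] (``clip``).
    """
    n = ct.n
    se_t, sp_t, pi = invert_joint_rates(
        ct.tp / n, ct.fp / n, ct.n_pos / n, se_r, sp_r)
    in_range = all(0.0 <= v <= 1.0 for v in (se_t, sp_t, pi)
                   if not math.isnan(v)) and not any(
        math.isnan(v) for v in (se_t, sp_t, pi))
    if in_range:
        return CorrectedDraw(se_t, sp_t, pi, valid=True)
    if invalid_policy == "discard":
        return CorrectedDraw(se_t, sp_t, pi, valid=False)
    clamp = lambda v: float(min(1.0, max(0.0, 0.0 if math.isnan(v) else v)))
    return CorrectedDraw(clamp(se_t), clamp(sp_t), clamp(pi),
                         valid=True, clipped=True)


def perturb_labels_correction(
    cohort: Cohort,
    threshold: float,
    se_r: float,
    sp_r: float,
    rng: np.random.Generator,
    max_redraws: int = 1000,
) -> tuple[float, float]:
    """Label-perturbation correction for one (se_r, sp_r) draw.

    Flip probabilities 1 - se_r (observed positives) and 1 - sp_r
    (observed negatives); Se/Sp of the threshold rule are recomputed
    against the perturbed labels. Perturbations that leave a single
    class are redrawn, up to ``max_redraws``.
    """
    observed = cohort.reference_labels()
    if observed.all() or not observed.any():
        raise ValueError("need both reference classes present")
    test_pos = cohort.hs_crp >= threshold
    for _ in range(max_redraws):
        u = rng.random(cohort.n)
        flipped = np.where(observed, u < (1.0 - se_r), u < (1.0 - sp_r))
        labels = observed ^ flipped
        n_pos = int(labels.sum())
        if n_pos == 0 or n_pos == cohort.n:
            continue
        se = float(np.sum(test_pos & labels) / n_pos)
        sp = float(np.sum(~test_pos & ~labels) / (cohort.n - n_pos))
        return se, sp
    raise RuntimeError(f"single-class perturbed labeling in {max_redraws} "
                       f"consecutive draws")


def monte_carlo_correction(
    data: Union[ConfusionTable, Cohort],
    threshold: Optional[float],
    assumption: ReferenceAssumption,
    keep_draws: bool = False,
    quartile_rule: str = "linear",
) -> CorrectionSummary:
    """Run the full Monte Carlo correction and summarize the draws.

    ``data`` is a confusion table (sufficient for the algebraic model)
    or a cohort, in which case ``threshold`` builds the table / the
    threshold rule. Valid draws are summarized by median and quartiles
    under the same quartile rule as cohort summaries; invalid draws
    (algebraic model, discard policy) are counted. With all draws
    invalid an empty, flagged summary is returned.
    """
    from .cohort import _NUMPY_METHOD  # shared quartile conventions

    if isinstance(data, Cohort):
        if threshold is None:
            raise ValueError("threshold required with a cohort input")
        cohort: Optional[Cohort] = data
        ct = classify_at_threshold(data, threshold)
    else:
        cohort = None
        ct = data
    if assumption.model == "label_perturbation" and cohort is None:
        raise ValueError("label_perturbation requires the full cohort")

    rng = np.random.default_rng(assumption.seed)
    ref_draws = sample_reference_performance(assumption, rng)
    rows = np.full((assumption.n_iterations, 5), np.nan)
    for i, (se_r, sp_r) in enumerate(ref_draws):
        if assumption.model == "algebraic_inversion":
            draw = invert_misclassification(ct, se_r, sp_r,
                                            assumption.invalid_policy)
            rows[i] = (se_r, sp_r, draw.se_t, draw.sp_t, float(draw.valid))
        else:
            se_t, sp_t = perturb_labels_correction(
                cohort, threshold, se_r, sp_r, rng)
            rows[i] = (se_r, sp_r, se_t, sp_t, 1.0)

    valid = rows[:, 4] == 1.0
    n_valid = int(valid.sum())
    n_invalid = assumption.n_iterations - n_valid
    method = _NUMPY_METHOD[quartile_rule]
    if n_valid == 0:
        se_summary = sp_summary = (math.nan, math.nan, math.nan)
    else:
        se_q = np.quantile(rows[valid, 2], [0.5, 0.25, 0.75], method=method)
        sp_q = np.quantile(rows[valid, 3], [0.5, 0.25, 0.75], method=method)
        se_summary = tuple(float(v) for v in se_q)
        sp_summary = tuple(float(v) for v in sp_q)
    return CorrectionSummary(
        model=assumption.model,
        corrected_se=se_summary,
        corrected_sp=sp_summary,
        n_valid=n_valid,
        n_invalid=n_invalid,
        n_iterations=assumption.n_iterations,
        invalid_policy=assumption.invalid_policy,
        draws=rows if keep_draws else None,
    )
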