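"""End-to-end analysis pipeline and report rendering.

``run_pipeline`` executes the full diagnostic-accuracy analysis on one
cohort — descriptive summary, Spearman correlations (vs the ordinal
category and vs VAS) with permutation p-values and bootstrap CIs, ROC
with a stratified-bootstrap AUC interval and the Youden-optimal
threshold, the multi-threshold accuracy table, the Monte Carlo
imperfect-reference correction, and the Shapiro-Wilk normality
assessment. A single master seed deterministically derives every
module's seed, so an identical configuration replays byte-identically.

Reports render to JSON (full precision; non-finite numbers become
explicit null-with-reason objects) or to an aligned plain-text table
whose columns follow the conventional accuracy-table order; undefined
or infinite quantities print as "(-)". Text percentages are rounded
half-up to whole percent; JSON always carries full precision.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, is_dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Any, Optional, Sequence

import numpy as np

from . import association, metrics, roc
from .cohort import Cohort, read_cohort, summarize_cohort
from .reference_correction import ReferenceAssumption, monte_carlo_correction

__all__ = ["AnalysisConfig", "AnalysisReport", "run_pipeline",
           "render_report", "SCHEMA_VERSION"]

SCHEMA_VERSION = "1.0"


@dataclass(frozen=True)
class AnalysisConfig:
    """Settings for one full pipeline run.

    ``seed`` is the master seed: per-stage seeds are spawned from it via
    ``numpy.random.SeedSequence``, so one integer pins every stochastic
    component.
    """

    thresholds: tuple[float, ...] = (2.9, 3.4, 3.5)
    ci_method: str = "wilson"
    confidence: float = 0.95
    bootstrap_b: int = 10_000
    p_method: str = "permutation"
    mc_se_range: tuple[float, float] = (0.75, 0.90)
    mc_sp_range: tuple[float, float] = (0.60, 0.80)
    mc_iterations: int = 10_000
    mc_model: str = "algebraic_inversion"
    mc_invalid_policy: str = "discard"
    quartile_rule: str = "linear"
    seed: int = 20_250_307

    def stage_seeds(self) -> dict[str, int]:
        ss = np.random.SeedSequence(self.seed)
        names = ("correlation_category", "correlation_vas", "roc_bootstrap",
                 "monte_carlo")
        states = ss.spawn(len(names))
        return {name: int(child.generate_state(1)[0] % (2 ** 31))
                for name, child in zip(names, states)}


@dataclass(frozen=True)
class AnalysisReport:
    schema_version: str
    config: AnalysisConfig
    cohort_provenance: str
    cohort_summary: Any
    correlation_category: association.CorrelationResult
    correlation_vas: association.CorrelationResult
    roc_curve: roc.RocCurve
    youden: tuple[float, float]
    threshold_metrics: tuple[metrics.MetricSet, ...]
    correction: Any
    normality: association.NormalityResult


def run_pipeline(config: AnalysisConfig, cohort: Cohort) -> AnalysisReport:
    """Execute the full analysis; deterministic under the master seed."""
    seeds = config.stage_seeds()

    summary = summarize_cohort(cohort, config.quartile_rule)

    corr_cat = association.spearman_with_inference(
        cohort.hs_crp, cohort.pain_category, p_method=config.p_method,
        b=config.bootstrap_b, confidence=config.confidence,
        seed=seeds["correlation_category"])
    corr_vas = association.spearman_with_inference(
        cohort.hs_crp, cohort.vas, p_method=config.p_method,
        b=config.bootstrap_b, confidence=config.confidence,
        seed=seeds["correlation_vas"])

    curve = roc.empirical_roc(cohort)
    ci = roc.auc_bootstrap_ci(cohort, b=config.bootstrap_b,
                              confidence=config.confidence,
                              seed=seeds["roc_bootstrap"])
    curve = roc.RocCurve(
        operating_points=curve.operating_points, auc=curve.auc,
        n_pos=curve.n_pos, n_neg=curve.n_neg, auc_ci=ci)
    youden = roc.youden_optimal(curve)

    table = tuple(metrics.threshold_report(
        cohort, config.thresholds, ci_method=config.ci_method,
        confidence=config.confidence))

    assumption = ReferenceAssumption(
        se_range=config.mc_se_range, sp_range=config.mc_sp_range,
        n_iterations=config.mc_iterations, model=config.mc_model,
        invalid_policy=config.mc_invalid_policy, seed=seeds["monte_carlo"])
    correction = monte_carlo_correction(
        cohort, config.thresholds[1] if len(config.thresholds) > 1
        else config.thresholds[0],
        assumption, quartile_rule=config.quartile_rule)

    normality = association.shapiro_wilk(cohort.hs_crp)

    return AnalysisReport(
        schema_version=SCHEMA_VERSION,
        config=config,
        cohort_provenance=cohort.provenance,
        cohort_summary=summary,
        correlation_category=corr_cat,
        correlation_vas=corr_vas,
        roc_curve=curve,
        youden=youden,
        threshold_metrics=table,
        correction=correction,
        normality=normality,
    )


# ---------------------------------------------------------------------------
# serialization

def _jsonable(obj: Any) -> Any:
    """Recursively convert to JSON-serializable structures.

    Non-finite floats become explicit null-with-reason objects so that
    the JSON stream is lossless about *why* a value is absent.
    """
    if is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in vars(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (float, np.floating)):
        f = float(obj)
        if math.isnan(f):
            return {"value": None, "reason": "undefined"}
        if math.isinf(f):
            return {"value": None, "reason": "infinite",
                    "sign": 1 if f > 0 else -1}
        return f
    return obj


def _pct(p: Optional[float]) -> str:
    """Round a proportion half-up to whole percent, as display convention."""
    if p is None or (isinstance(p, float) and not math.isfinite(p)):
        return "-"
    return str(int(Decimal(p * 100).quantize(Decimal("1"),
                                             rounding=ROUND_HALF_UP)))


def _fmt_prop(ci: Optional[metrics.ProportionCI]) -> str:
    if ci is None:
        return "(–)"
    return f"{_pct(ci.estimate)}% ({_pct(ci.lower)}–{_pct(ci.upper)})"


def _fmt_lr(lr: metrics.LikelihoodRatio) -> str:
    if not lr.defined:
        return "(–)"
    value = "inf" if not lr.finite else f"{lr.value:.2f}"
    if lr.lower is None or lr.upper is None:
        return f"{value} (–)"
    return f"{value} ({lr.lower:.2f}–{lr.upper:.2f})"


def render_report(report: AnalysisReport, format: str = "json") -> str:
    """Serialize a report. ``json`` round-trips losslessly (parse and
    re-dump reproduce identical bytes); ``text`` is a human-readable
    summary with the aligned accuracy table."""
    if format == "json":
        return json.dumps(_jsonable(report), indent=2, sort_keys=True)
    if format != "text":
        raise ValueError(f"unknown format {format!r}")

    s = report.cohort_summary
    lines = [
        f"Cohort: n={s.n}, categories none/mild/moderate/severe = "
        f"{'/'.join(str(c) for c in s.category_counts)}",
        f"hs-CRP: median {s.median:.2f} mg/L, IQR {s.q1:.2f}-{s.q3:.2f}, "
        f"max {s.maximum:.1f}; VAS mean {s.vas_mean:.1f} +/- {s.vas_sd:.1f} cm",
        f"Spearman rho vs pain category: {report.correlation_category.rho:.3f}"
        f" (95% CI {report.correlation_category.ci[0]:.2f}-"
        f"{report.correlation_category.ci[1]:.2f}, "
        f"p={report.correlation_category.p_value:.4g})",
        f"Spearman rho vs VAS: {report.correlation_vas.rho:.3f}"
        f" (95% CI {report.correlation_vas.ci[0]:.2f}-"
        f"{report.correlation_vas.ci[1]:.2f}, "
        f"p={report.correlation_vas.p_value:.4g})",
        f"AUC: {report.roc_curve.auc:.3f}"
        + (f" (95% CI {report.roc_curve.auc_ci[0]:.3f}-"
           f"{report.roc_curve.auc_ci[1]:.3f})"
           if report.roc_curve.auc_ci else ""),
        f"Youden-optimal threshold: {report.youden[0]:.2f} mg/L "
        f"(J={report.youden[1]:.3f})",
        f"Shapiro-Wilk: W={report.normality.w_statistic:.2f}, "
        f"p={report.normality.p_value:.3g}",
        "",
    ]
    header = ["Threshold (mg/L)", "Sensitivity (95% CI)",
              "Specificity (95% CI)", "LR+ (95% CI)", "LR- (95% CI)",
              "PPV", "NPV"]
    rows = [header]
    for m in report.threshold_metrics:
        rows.append([
            f"{m.threshold:g}",
            _fmt_prop(m.sensitivity),
            _fmt_prop(m.specificity),
            _fmt_lr(m.lr_pos),
            _fmt_lr(m.lr_neg),
            f"{_pct(m.ppv.estimate)}%" if m.ppv else "(–)",
            f"{_pct(m.npv.estimate)}%" if m.npv else "(–)",
        ])
    widths = [max(len(r[i]) for r in rows) for i in range(len(header))]
    for r in rows:
        lines.append("  ".join(cell.ljust(w) for cell, w in zip(r, widths))
                     .rstrip())
    c = report.correction
    lines += [
        "",
        f"Imperfect-reference correction ({c.model}, {c.invalid_policy}): "
        f"corrected Se median {_pct(c.corrected_se[0])}% "
        f"(IQR {_pct(c.corrected_se[1])}-{_pct(c.corrected_se[2])}%), "
        f"Sp median {_pct(c.corrected_sp[0])}% "
        f"(IQR {_pct(c.corrected_sp[1])}-{_pct(c.corrected_sp[2])}%); "
        f"valid {c.n_valid}/{c.n_iterations}",
    ]
    return "\n".join(lines) + "\n"
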