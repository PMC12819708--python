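# Methods

## Setting and data model

The package analyzes a pilot-scale diagnostic-accuracy cohort: adults with
symptomatic irreversible pulpitis, each contributing one pulpal-blood hs-CRP
measurement (point-of-care fluorescent immunoassay, quantitation range
0.5–200 mg/L, coefficient of variation under 10%), a 0–10 cm VAS pain score,
and an ordinal pain category (none/mild/moderate/severe). The reference
condition throughout is *severe pain*, i.e. category ≥ 3.

Concentrations below the 0.5 mg/L limit of detection are stored as 0.0 with
an explicit `below_lod` flag, and enter every rank-based and threshold
computation as 0.0. This coding is what makes an interquartile range with a
lower bound of exactly 0.0 representable, and it is conservative for
threshold classification (censored values can never test positive at any
threshold ≥ LOD).

## The reconstructed 13-subject cohort

The raw per-patient values of the motivating pilot study are not published.
The shipped fixture (`canonical_fixture()`, also
`src/pulpdta/fixtures/pilot_cohort.csv`) is a **synthetic reconstruction**
built to satisfy every printed classification constraint simultaneously:
2 mild / 5 moderate / 6 severe; four non-severe undetectables; all six severe
values ≥ 3.4 with exactly one in [3.4, 3.5); exactly two non-severe values
≥ 2.9, of which exactly one ≥ 3.5; maximum 18.0 mg/L. These constraints force
the 2×2 tables (6,2,0,5), (6,1,0,6) and (5,1,1,6) at the three reported
thresholds.

Two published summaries cannot both hold: six severe values ≥ 3.4 plus one
false positive place the 7th of 13 order statistics at ≥ 3.4, so no
pattern-consistent cohort has median 2.9 mg/L. The fixture prioritizes the
classification pattern; its median is 3.45 mg/L. For the same reason the
published ρ = 0.918, AUC = 0.944 and W = 0.82 are not exactly recoverable
from any pattern-consistent reconstruction — the fixture yields ρ ≈ 0.757,
AUC ≈ 0.905 and W ≈ 0.81, which reproduce the findings qualitatively (strong
monotone association, excellent discrimination, clear non-normality) but are
not numeric targets. VAS values are a plausible monotone reconstruction
(mean 6.85 cm, SD 2.49 cm).

## Synthetic cohort generator

`generate_cohort(SyntheticConfig(...))` draws, per subject:

1. a pain category from `category_probs` (default (0, 2/13, 5/13, 6/13),
   the observed cohort mix — no pain-free subjects, since enrollment
   required symptomatic pulpitis);
2. with probability `undetectable_prob_by_category[cat]` (default
   0.90/0.70/0.40/0.05, non-increasing by construction), a structural
   undetectable (0.0, flagged);
3. otherwise a log-normal true concentration with log-mean
   `location_by_category[cat]` (default −1.0/0.1/1.0/1.7 log mg/L, i.e.
   category medians ≈ 0.37/1.1/2.7/5.5 mg/L, non-decreasing by construction)
   and log-SD `sigma_log` (default 0.6), multiplied by mean-one log-normal
   assay noise with CV `assay_cv` (default 0.10, the assay's stated
   precision class), then left-censored at `lod` (default 0.5) and clipped
   at 200 mg/L with an over-range flag;
4. VAS = 2.5 + 2.0·category + N(0, `vas_noise_sd`²) clamped to [0, 10]
   (default SD 1.5). Under the default mixture this map gives population
   VAS mean ≈ 7.1 cm and SD ≈ 2.1 cm, matching the reported 7.1 ± 2.4 cm
   closely; any monotone map would do, this one is the simplest.

The default log-locations are set high enough that detected concentrations
rarely fall below the LOD, so the below-LOD fraction tracks the configured
structural mixture (≈ 0.29) to within about half a percentage point — this
keeps the structural-undetectable probabilities interpretable as *the*
censoring rates. The generator emulates the marginal and dose-response
structure of the pilot data; it does **not** model within-patient assay
duplicates, sex, age, tooth anatomy, anesthesia effects, or any correlation
between VAS noise and biomarker noise. Tests that pass on generated cohorts
therefore validate the statistical machinery under the assumed mixture, not
the biology of real pulpal blood.

## Statistical procedures

**Threshold metrics.** Positivity is inclusive (marker ≥ threshold), so ties
at the threshold are positive. Wilson score intervals are the table default;
Clopper–Pearson exact intervals (beta-quantile tail inversion) are selectable
— both appear in the motivating analysis, whose printed 6/6 lower bounds
(61% vs 54%) identify the two methods. Likelihood-ratio CIs use the standard
log-method; a Haldane policy (add 0.5 to every cell) is available for
zero-cell tables, and under the exact policy zero cells produce explicit
0 / +inf / NaN flags rather than exceptions. Post-test probabilities use the
odds form of Bayes' rule and are exactly consistent with PPV and 1 − NPV
when the pretest probability is the sample prevalence. Degenerate
(single-reference-class) cohorts yield flagged, partially-undefined metric
sets.

**ROC.** AUC is the tie-aware Mann–Whitney statistic (ties 0.5), computed
via pooled mid-ranks; it equals trapezoidal integration of the empirical
curve to machine precision, which the tests assert. AUC intervals are
stratified percentile bootstrap (resampling within each reference class, so
no resample is degenerate); DeLong variance and smoothed ROC fits are out of
scope. Operating-point thresholds are realized marker values, not midpoints.
Youden ties break toward the larger threshold, favoring specificity.

**Rank correlation.** Spearman's ρ is the Pearson correlation of mid-ranks;
the ordinal pain scale guarantees heavy ties, so the tie convention is
material. The default p-value is a permutation test with the add-one
correction (1 + hits)/(1 + B), exact in the limit and honest at n = 13; an
exhaustive enumeration is available for n ≤ 8 and the asymptotic t
approximation (n − 2 df) for comparability. Confidence intervals are
percentile bootstrap over subject pairs; resamples with an undefined
statistic (a constant variable) are redrawn, capped at 100 consecutive
failures. Percentile bootstrap is known to undercover at n = 13; the
acceptance suite verifies ≥ 85% empirical coverage at a nominal 95%.

**Normality.** Shapiro–Wilk delegates to scipy's implementation of Royston's
approximation (valid 3 ≤ n ≤ 5000). Q-Q series use Blom-type
(i − 0.375)/(n + 0.25) plotting positions; histograms use the
Freedman–Diaconis bin rule.

**Imperfect-reference correction.** The motivating analysis names neither a
correction formula nor an independence assumption, so two defensible models
are implemented and the model identifier is mandatory in every output:

- *Algebraic inversion* assumes conditional independence of index and
  reference errors given the true state and solves the 2-equation linear
  system for (π·Se_t, (1−π)(1−Sp_t)) from the observed joint rates, with
  π = (q + Sp_r − 1)/(Se_r + Sp_r − 1). It recovers generating parameters
  exactly from noiseless forward-composed rates (asserted), but at n = 13
  with apparent Se = 100% the solution exceeds 1 for essentially every draw
  in the plausible reference range — those draws are discarded and counted
  (default) or clamped (clip policy). On the reconstructed pilot table the
  invalid fraction is ~100%, which the pipeline reports honestly rather than
  summarizing an empty distribution.
- *Label perturbation* treats observed labels as noisy (flip probabilities
  1 − Se_r, 1 − Sp_r) and recomputes accuracy against perturbed labels;
  single-class perturbations are redrawn (cap 1000).

Reference performance is drawn uniformly and independently over the stated
ranges (defaults Se_r ∈ [0.75, 0.90], Sp_r ∈ [0.60, 0.80]; ranges are all
the source material states, so no beta shape is invented), 10,000 iterations
by default, summarized by median and quartiles. The published corrected
medians (Se 56%, Sp 83%) are reproducible under neither model from the
reconstructed table and are not targets.

## Numerical conventions

- Quartiles: linear interpolation of order statistics (numpy's default,
  R type 7), selectable per call; the same rule is used for cohort summaries
  and Monte Carlo draw summaries.
- Wilson bounds at k = 0 and k = n are snapped to the analytic 0 and 1
  (the closed form reaches them only up to round-off).
- Percentages in text reports are rounded half-up to whole percent;
  JSON always carries full precision, with non-finite values serialized as
  explicit null-with-reason objects. Undefined/infinite quantities render
  as "(–)" in text.
- Determinism: one master seed per pipeline run spawns per-stage seeds via
  `numpy.random.SeedSequence`; identical configurations produce
  byte-identical JSON reports, which a test asserts.
- CSV round-trips are exact: floats are written with `repr`, which
  round-trips IEEE doubles.

## Problem sizes used in validation

The test and acceptance suites use: 500 random tied cohorts for the
AUC-oracle equivalence; 100 null seeds at n = 200 with B = 2000 permutations
for p-value calibration; 300 generator seeds at the study size n = 13 with
B = 1000 bootstrap resamples, against the large-sample ρ computed on an
n = 100,000 cohort, for interval coverage; n = 2000 forward-simulated
cohorts for misclassification-inversion recovery (±0.03). The pipeline
defaults themselves keep the analysis-scale settings (B = 10,000 resamples,
10,000 Monte Carlo iterations).

## Known limitations

- The fixture is a constrained reconstruction, not the real cohort; all
  fixture-derived statistics carry that caveat.
- The generator's measurement model is a single multiplicative log-normal
  noise term; duplicate-measurement averaging and instrument drift are not
  modeled.
- Percentile bootstrap (ρ, AUC) undercovers at pilot sample sizes;
  bias-corrected variants are deliberately out of scope.
- The algebraic correction is non-informative for this cohort size and
  apparent-accuracy profile (near-total invalid draws); conclusions about
  corrected accuracy should rest on the label-perturbation model or on
  larger cohorts.
- Kendall's τ, DeLong AUC variance, latent-class reference models, and any
  figure rendering beyond data series are out of scope.
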