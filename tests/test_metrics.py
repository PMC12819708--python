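"""Threshold classification, binomial intervals, likelihood ratios,
Bayes updating, and the multi-threshold report."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy import stats

from pulpdta.cohort import canonical_fixture
from pulpdta.metrics import (
    ConfusionTable,
    classify_at_threshold,
    clopper_pearson_interval,
    likelihood_ratios,
    posttest_probability,
    proportion_metrics,
    threshold_report,
    wilson_interval,
)

from conftest import make_cohort


class TestClassify:
    @pytest.mark.parametrize("threshold,cells", [
        (2.9, (6, 2, 0, 5)),
        (3.4, (6, 1, 0, 6)),
        (3.5, (5, 1, 1, 6)),
        (0.0, (6, 7, 0, 0)),       # all test-positive
        (1000.0, (0, 0, 6, 7)),    # all test-negative
    ])
    def test_fixture_tables(self, fixture_cohort, threshold, cells):
        ct = classify_at_threshold(fixture_cohort, threshold)
        assert (ct.tp, ct.fp, ct.fn, ct.tn) == cells
        assert ct.n == 13

    def test_positivity_is_inclusive_at_the_threshold(self):
        cohort = make_cohort([3.4], [3.4, 1.0])
        ct = classify_at_threshold(cohort, 3.4)
        assert (ct.tp, ct.fp, ct.fn, ct.tn) == (1, 1, 0, 1)

    def test_threshold_sweep_monotone_and_conserving(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            pos = rng.integers(0, 8, size=rng.integers(1, 8)) / 2
            neg = rng.integers(0, 8, size=rng.integers(1, 8)) / 2
            cohort = make_cohort(pos, neg)
            sweep = sorted(set(np.concatenate([pos, neg])))
            prev_tp = prev_fp = math.inf
            for thr in sweep:
                ct = classify_at_threshold(cohort, thr)
                assert ct.n == len(pos) + len(neg)
                assert ct.tp <= prev_tp and ct.fp <= prev_fp
                prev_tp, prev_fp = ct.tp, ct.fp


class TestProportionMetrics:
    def test_threshold_29_table(self):
        m = proportion_metrics(ConfusionTable(6, 2, 0, 5))
        assert m["sensitivity"].estimate == 1.0
        assert m["specificity"].estimate == pytest.approx(5 / 7)
        assert m["ppv"].estimate == pytest.approx(0.75)
        assert m["npv"].estimate == 1.0

    def test_threshold_35_table(self):
        m = proportion_metrics(ConfusionTable(5, 1, 1, 6))
        assert m["sensitivity"].estimate == pytest.approx(5 / 6)
        assert m["ppv"].estimate == pytest.approx(5 / 6)

    def test_zero_denominator_is_undefined_not_fatal(self):
        m = proportion_metrics(ConfusionTable(0, 0, 0, 10))
        assert m["sensitivity"] is None
        assert m["ppv"] is None
        assert m["specificity"].estimate == 1.0

    def test_naive_per_record_oracle_agrees(self, fixture_cohort):
        # recount everything with an explicit python loop
        for thr in (0.5, 2.9, 3.4, 3.5, 9.0):
            tp = fp = fn = tn = 0
            for rec in fixture_cohort.records:
                test_pos = rec.hs_crp >= thr
                ref_pos = rec.pain_category >= 3
                tp += test_pos and ref_pos
                fp += test_pos and not ref_pos
                fn += (not test_pos) and ref_pos
                tn += (not test_pos) and not ref_pos
            ct = classify_at_threshold(fixture_cohort, thr)
            assert (ct.tp, ct.fp, ct.fn, ct.tn) == (tp, fp, fn, tn)
            m = proportion_metrics(ct)
            assert m["sensitivity"].estimate == tp / (tp + fn)
            assert m["specificity"].estimate == tn / (tn + fp)
            lr_pos, _ = likelihood_ratios(ct)
            expected = ((tp / (tp + fn)) / (fp / (fp + tn)) if fp > 0
                        else math.inf)
            assert lr_pos.value == expected


class TestWilson:
    def test_perfect_six_of_six_lower_bound(self):
        ci = wilson_interval(6, 6, 0.95)
        z = stats.norm.ppf(0.975)
        assert ci.lower == pytest.approx(0.6097, abs=5e-5)
        assert ci.lower == pytest.approx(6 / (6 + z * z), abs=1e-12)
        assert ci.upper == 1.0

    def test_complement_symmetry(self):
        for k, n in [(0, 6), (2, 9), (5, 7)]:
            a = wilson_interval(k, n)
            b = wilson_interval(n - k, n)
            assert a.lower == pytest.approx(1 - b.upper, abs=1e-12)
            assert a.upper == pytest.approx(1 - b.lower, abs=1e-12)

    def test_five_of_seven(self):
        ci = wilson_interval(5, 7, 0.95)
        assert ci.lower == pytest.approx(0.35893, abs=5e-5)
        assert ci.upper == pytest.approx(0.91778, abs=5e-5)


class TestClopperPearson:
    def test_perfect_six_of_six_lower_bound(self):
        ci = clopper_pearson_interval(6, 6, 0.95)
        assert ci.lower == pytest.approx(0.025 ** (1 / 6), abs=1e-12)
        assert ci.lower == pytest.approx(0.5407, abs=5e-5)
        assert ci.upper == 1.0

    def test_zero_of_six_complement(self):
        ci = clopper_pearson_interval(0, 6, 0.95)
        assert ci.lower == 0.0
        assert ci.upper == pytest.approx(1 - 0.025 ** (1 / 6), abs=1e-12)

    def test_five_of_seven_against_tail_inversion_oracle(self):
        # invert the exact binomial tails by bisection, independently:
        # P(X >= k | p) rises with p, P(X <= k | p) falls with p.
        def bisect(f, target, increasing):
            lo, hi = 0.0, 1.0
            for _ in range(80):
                mid = (lo + hi) / 2
                below = f(mid) < target
                if below == increasing:
                    lo = mid
                else:
                    hi = mid
            return (lo + hi) / 2

        k, n = 5, 7
        lower = bisect(lambda p: stats.binom.sf(k - 1, n, p), 0.025, True)
        upper = bisect(lambda p: stats.binom.cdf(k, n, p), 0.025, False)
        ci = clopper_pearson_interval(k, n, 0.95)
        assert ci.lower == pytest.approx(lower, abs=1e-9)
        assert ci.upper == pytest.approx(upper, abs=1e-9)
        assert ci.lower == pytest.approx(0.2904, abs=5e-5)
        assert ci.upper == pytest.approx(0.9633, abs=5e-5)


class TestIntervalSanity:
    @pytest.mark.parametrize("method", [wilson_interval,
                                        clopper_pearson_interval])
    def test_contains_estimate_and_shrinks_with_n(self, method):
        for k, n in [(3, 10), (7, 9), (1, 50)]:
            small = method(k, n)
            big = method(10 * k, 10 * n)
            assert small.lower <= small.estimate <= small.upper
            assert (big.upper - big.lower) < (small.upper - small.lower)


class TestLikelihoodRatios:
    def test_table1_row_29(self):
        lr_pos, lr_neg = likelihood_ratios(ConfusionTable(6, 2, 0, 5))
        assert lr_pos.value == pytest.approx(3.50)
        # log-method CI with SE = sqrt(1/6 - 1/6 + 1/2 - 1/7)
        assert lr_pos.lower == pytest.approx(1.085, abs=2e-3)
        assert lr_pos.upper == pytest.approx(11.29, abs=2e-2)
        assert lr_neg.value == 0.0
        assert lr_neg.lower is None

    def test_zero_false_negatives_gives_lr_neg_zero(self):
        _, lr_neg = likelihood_ratios(ConfusionTable(6, 1, 0, 6))
        assert lr_neg.value == 0.0

    def test_zero_false_positives_gives_infinite_lr_pos(self):
        lr_pos, _ = likelihood_ratios(ConfusionTable(6, 0, 1, 6))
        assert math.isinf(lr_pos.value)
        assert not lr_pos.finite

    def test_haldane_policy_matches_hand_formula(self):
        ct = ConfusionTable(6, 0, 1, 6)
        lr_pos, _ = likelihood_ratios(ct, zero_cell_policy="haldane")
        se = 6.5 / 8.0
        one_minus_sp = 0.5 / 7.0
        assert lr_pos.value == pytest.approx(se / one_minus_sp)
        assert lr_pos.lower is not None and lr_pos.lower < lr_pos.value

    def test_undefined_zero_over_zero(self):
        lr_pos, _ = likelihood_ratios(ConfusionTable(0, 0, 6, 7))
        assert math.isnan(lr_pos.value)
        assert not lr_pos.defined


class TestPosttest:
    def test_printed_update_46_to_86(self):
        prev = 6 / 13
        assert prev == pytest.approx(0.4615, abs=5e-5)
        post = posttest_probability(prev, 7.0)  # LR+ of the (6,1,0,6) table
        assert post == pytest.approx(6 / 7)
        assert round(post * 100) == 86

    def test_uninformative_and_pathological_lrs(self):
        assert posttest_probability(0.3, 1.0) == pytest.approx(0.3)
        assert posttest_probability(6 / 13, 0.0) == 0.0
        assert posttest_probability(0.5, math.inf) == 1.0

    @pytest.mark.parametrize("pretest", [0.0, 1.0, -0.2, 1.3])
    def test_degenerate_pretest_rejected(self, pretest):
        with pytest.raises(ValueError):
            posttest_probability(pretest, 2.0)

    def test_bayes_identity_on_random_tables(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            ct = ConfusionTable(*(int(v) for v in rng.integers(1, 30, 4)))
            prev = ct.prevalence
            lr_pos, lr_neg = likelihood_ratios(ct)
            ppv = ct.tp / (ct.tp + ct.fp)
            npv = ct.tn / (ct.tn + ct.fn)
            assert posttest_probability(prev, lr_pos.value) == pytest.approx(
                ppv, abs=1e-12)
            assert posttest_probability(prev, lr_neg.value) == pytest.approx(
                1 - npv, abs=1e-12)


class TestThresholdReport:
    def test_fixture_three_rows(self, fixture_cohort):
        rows = threshold_report(fixture_cohort, [2.9, 3.4, 3.5])
        assert [r.threshold for r in rows] == [2.9, 3.4, 3.5]
        assert rows[0].ppv.estimate == pytest.approx(0.75)
        assert rows[0].npv.estimate == 1.0
        assert rows[0].posttest_pos == pytest.approx(0.75, abs=1e-12)

    def test_threshold_zero_all_positive(self, fixture_cohort):
        (row,) = threshold_report(fixture_cohort, [0.0])
        assert row.sensitivity.estimate == 1.0
        assert row.specificity.estimate == 0.0

    def test_huge_threshold_all_negative(self, fixture_cohort):
        (row,) = threshold_report(fixture_cohort, [1000.0])
        assert row.sensitivity.estimate == 0.0
        assert row.npv.estimate == pytest.approx(7 / 13)
        assert not row.lr_pos.defined  # 0/0

    def test_single_class_cohort_degrades_gracefully(self):
        cohort = make_cohort([1.0, 2.0, 3.0], [])
        (row,) = threshold_report(cohort, [2.0])
        assert row.degenerate
        assert row.specificity is None
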