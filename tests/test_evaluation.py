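"""Unit tests for metrics, BH adjustment, and ratio-marker analysis."""

import numpy as np
import pytest
from scipy import stats

from metabopanel import synthetic_data as synth
from metabopanel.evaluation import (
    bh_adjust,
    confusion_metrics,
    group_difference_test,
    mean_ci,
    pr_curve,
    ratio_marker_analysis,
    roc_auc,
)
from oracles import auc_pairwise, bh_rejections


class TestConfusionMetrics:
    def test_perfect_predictor(self):
        y = np.array([1, -1, 1, -1, 1, 1, -1, -1, 1, -1])
        cm = confusion_metrics(y, y)
        assert (cm.accuracy, cm.sensitivity, cm.specificity) == (1.0, 1.0, 1.0)

    def test_hand_counted_example(self):
        # TP=2 FP=1 TN=3 FN=4
        y_true = np.array([1, 1, 1, 1, 1, 1, -1, -1, -1, -1])
        y_pred = np.array([1, 1, -1, -1, -1, -1, 1, -1, -1, -1])
        cm = confusion_metrics(y_true, y_pred)
        assert (cm.tp, cm.fp, cm.tn, cm.fn) == (2, 1, 3, 4)
        assert cm.accuracy == 0.5
        assert cm.sensitivity == pytest.approx(1 / 3)
        assert cm.specificity == 0.75

    def test_always_positive_predictor(self):
        y_true = np.array([1, -1, -1, 1])
        cm = confusion_metrics(y_true, np.ones(4, dtype=int))
        assert cm.sensitivity == 1.0 and cm.specificity == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(np.array([]), np.array([]))


class TestRocAuc:
    def test_perfect_separation(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        labels = np.array([-1, -1, 1, 1])
        assert roc_auc(scores, labels).auc == 1.0

    def test_four_point_toy_by_pair_enumeration(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8])
        labels = np.array([-1, -1, 1, 1])
        roc = roc_auc(scores, labels)
        assert roc.auc == pytest.approx(0.75)
        assert roc.auc == pytest.approx(auc_pairwise(scores, labels))

    def test_null_scores_near_half(self, rng):
        scores = rng.normal(size=2000)
        labels = np.where(rng.random(2000) < 0.5, 1, -1)
        se = np.sqrt((2000 + 1) / (12 * np.sum(labels == 1) * np.sum(labels == -1)))
        assert abs(roc_auc(scores, labels).auc - 0.5) < 3 * se

    def test_mann_whitney_identity_with_ties(self, rng):
        for _ in range(100):
            n = int(rng.integers(8, 60))
            scores = rng.integers(0, 6, size=n).astype(float)  # heavy ties
            labels = np.where(rng.random(n) < 0.5, 1, -1)
            if len(set(labels)) < 2:
                labels[0] = -labels[0]
            auc = roc_auc(scores, labels).auc
            assert auc == pytest.approx(auc_pairwise(scores, labels), abs=1e-12)

    def test_curve_endpoints(self, rng):
        scores = rng.normal(size=50)
        labels = np.where(rng.random(50) < 0.4, 1, -1)
        labels[:2] = [1, -1]
        roc = roc_auc(scores, labels)
        assert (roc.fpr[0], roc.tpr[0]) == (0.0, 0.0)
        assert (roc.fpr[-1], roc.tpr[-1]) == (1.0, 1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([1.0, 2.0]), np.array([1, 1]))


class TestPrCurve:
    def test_perfect_separation_precision_one(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        labels = np.array([-1, -1, 1, 1])
        pr = pr_curve(scores, labels)
        # upper envelope: every achieved recall is reachable at precision 1
        for r in np.unique(pr.recall[pr.recall > 0]):
            assert pr.precision[pr.recall == r].max() == 1.0
        assert pr.average_precision == 1.0

    def test_four_point_toy_enumeration(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8])
        labels = np.array([-1, -1, 1, 1])
        pr = pr_curve(scores, labels)
        pts = set(zip(np.round(pr.recall, 6), np.round(pr.precision, 6)))
        # thresholds 0.8, 0.4, 0.35, 0.1 give these (recall, precision)
        for expected in [(0.5, 1.0), (0.5, 0.5), (1.0, round(2 / 3, 6)), (1.0, 0.5)]:
            assert expected in pts
        assert pr.average_precision == pytest.approx(0.5 * 1.0 + 0.5 * 2 / 3)

    def test_recall_non_decreasing(self, rng):
        scores = rng.normal(size=40)
        labels = np.where(rng.random(40) < 0.5, 1, -1)
        labels[0] = 1
        pr = pr_curve(scores, labels)
        assert (np.diff(pr.recall) >= 0).all()

    def test_full_recall_point_has_prevalence_precision(self, rng):
        scores = rng.normal(size=200)
        labels = np.where(rng.random(200) < 0.3, 1, -1)
        pr = pr_curve(scores, labels)
        at_full = pr.precision[pr.recall == 1.0]
        assert at_full.min() == pytest.approx(np.mean(labels == 1))

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            pr_curve(np.array([1.0, 2.0]), np.array([-1, -1]))


class TestMeanCi:
    def test_constant_vector_zero_width(self):
        mean, lo, hi = mean_ci(np.full(10, 0.42))
        assert mean == pytest.approx(0.42)
        assert hi - lo == pytest.approx(0.0, abs=1e-15)

    def test_balanced_binary_closed_form(self):
        values = np.array([0.0, 1.0] * 1000)
        mean, lo, hi = mean_ci(values)
        assert mean == 0.5
        half = 1.959964 * values.std(ddof=1) / np.sqrt(2000)
        assert hi - mean == pytest.approx(half)
        assert hi - mean == pytest.approx(0.0219, abs=2e-4)

    def test_quadrupling_n_halves_width(self, rng):
        v = rng.normal(size=250)
        _, lo1, hi1 = mean_ci(v)
        v4 = np.tile(v, 4)
        _, lo4, hi4 = mean_ci(v4)
        # tiling quadruples n at (nearly) unchanged SD; ddof=1 shifts the
        # SD by ~1/(2n)
        assert (hi4 - lo4) == pytest.approx((hi1 - lo1) / 2, rel=5e-3)

    def test_percentile_option_brackets_distribution(self, rng):
        v = rng.normal(size=4000)
        _, lo, hi = mean_ci(v, method="percentile")
        assert lo == pytest.approx(np.quantile(v, 0.025))
        assert hi == pytest.approx(np.quantile(v, 0.975))
        # far wider than the CI of the mean at this n
        _, lo_m, hi_m = mean_ci(v)
        assert (hi - lo) > 10 * (hi_m - lo_m)

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            mean_ci([0.5])


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.031])[0] == pytest.approx(0.031)

    def test_stepup_arithmetic_by_hand(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_adjusted_never_below_raw(self, rng):
        p = rng.random(50)
        assert (bh_adjust(p) >= p).all()

    def test_rejection_sets_match_brute_force(self, rng):
        for _ in range(20):
            p = rng.random(int(rng.integers(3, 40)))
            adj = bh_adjust(p)
            for q in (0.01, 0.05, 0.1, 0.25):
                np.testing.assert_array_equal(adj <= q, bh_rejections(p, q))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestGroupDifferenceTest:
    def test_identical_groups(self):
        values = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        groups = np.array(["a", "a", "a", "b", "b", "b"])
        t, p = group_difference_test(values, groups)
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_label_swap_negates_t(self, rng):
        values = rng.normal(size=30)
        groups = np.array(["x"] * 15 + ["y"] * 15)
        t1, p1 = group_difference_test(values, groups)
        flipped = np.where(groups == "x", "z", "a")  # swaps sort order
        t2, p2 = group_difference_test(values, flipped)
        assert t2 == pytest.approx(-t1)
        assert p2 == pytest.approx(p1)

    def test_rejection_rate_matches_welch_power(self, rng):
        """Welch test at n=50/50 and true shift 1.0: empirical power
        matches the noncentral-t closed form."""
        n, d = 50, 1.0
        nc = d / np.sqrt(2 / n)
        df = 2 * n - 2
        tcrit = stats.t.ppf(0.975, df)
        power = 1 - stats.nct.cdf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc)
        rej = 0
        reps = 400
        for _ in range(reps):
            v = np.concatenate([rng.normal(0, 1, n), rng.normal(d, 1, n)])
            g = np.array(["a"] * n + ["b"] * n)
            _, p = group_difference_test(v, g)
            rej += p < 0.05
        se = np.sqrt(power * (1 - power) / reps)
        assert abs(rej / reps - power) < 4 * se

    def test_degenerate_group_rejected(self):
        with pytest.raises(ValueError):
            group_difference_test(np.array([1.0, 2.0, 3.0]),
                                  np.array(["a", "b", "b"]))


class TestRatioMarkerAnalysis:
    def test_degenerate_ratio_gives_half_auc(self):
        conc, _ = synth.generate_nac_cohort(synth.NacCohortSpec(), 1)
        out = ratio_marker_analysis(conc, "inosine", "inosine")
        assert (out["auc"] == 0.5).all()

    def test_scale_invariance(self):
        conc, _ = synth.generate_nac_cohort(synth.NacCohortSpec(), 2)
        base = ratio_marker_analysis(conc, "inosine", "uridine")
        conc.concentrations["inosine"] *= 37.0
        conc.concentrations["uridine"] *= 37.0
        scaled = ratio_marker_analysis(conc, "inosine", "uridine")
        np.testing.assert_allclose(scaled["auc"], base["auc"])

    def test_planted_tnbc_effect_ranks_tnbc_first(self):
        tnbc_wins = 0
        for s in range(5):
            conc, _ = synth.generate_nac_cohort(
                synth.NacCohortSpec(effect_d=1.5), 100 + s
            )
            out = ratio_marker_analysis(conc, "inosine", "uridine").set_index("stratum")
            if out.loc["TNBC", "auc"] > out.drop("TNBC")["auc"].max():
                tnbc_wins += 1
        assert tnbc_wins >= 4

    def test_missing_analyte_rejected(self):
        conc, _ = synth.generate_nac_cohort(synth.NacCohortSpec(), 3)
        with pytest.raises(ValueError):
            ratio_marker_analysis(conc, "caffeine", "uridine")
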