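"""Unit tests for SIL-IS calibration, acceptance rules, and quantification."""

import numpy as np
import pandas as pd
import pytest

from metabopanel import synthetic_data as synth
from metabopanel.targeted_quant import (
    CalibrationCurve,
    CalibrationError,
    back_calculate,
    calibrate_run,
    detection_limit,
    estimate_limits,
    fit_calibration,
    quantify,
    response_ratio,
    validate_curve,
)
from oracles import wls_normal_equations

LEVELS = np.array([0.5 * 2**k for k in range(13)])  # 13-level doubling series


def _ratios(slope, intercept, x, bias=None):
    r = slope * x + intercept
    if bias is not None:
        r = r * (1.0 + np.asarray(bias))
    return r


class TestResponseRatio:
    def test_division(self):
        assert response_ratio(5000.0, 10000.0) == 0.5

    def test_zero_analyte(self):
        assert response_ratio(0.0, 10000.0) == 0.0

    def test_gain_cancels(self):
        assert response_ratio(7.0 * 123, 3.0 * 123) == pytest.approx(7.0 / 3.0)

    def test_bad_is_area(self):
        with pytest.raises(ValueError, match="unquantifiable"):
            response_ratio(100.0, 0.0)


class TestFitCalibration:
    def test_noise_free_line_recovered_exactly(self):
        r = _ratios(0.02, 0.001, LEVELS)
        curve = fit_calibration(LEVELS, r, weighting_exponent=2)
        assert curve.slope == pytest.approx(0.02, rel=1e-12)
        assert curve.intercept == pytest.approx(0.001, abs=1e-12)
        assert curve.weighted_r2 == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("exponent", [0, 1, 2])
    def test_matches_normal_equations_oracle(self, exponent, rng):
        for _ in range(20):
            x = np.sort(rng.uniform(0.1, 100, size=13))
            r = _ratios(0.05, 0.01, x) * rng.lognormal(0, 0.05, size=13)
            curve = fit_calibration(x, r, weighting_exponent=exponent)
            slope, intercept = wls_normal_equations(x, r, exponent)
            assert curve.slope == pytest.approx(slope, rel=1e-10)
            assert curve.intercept == pytest.approx(intercept, rel=1e-10, abs=1e-14)

    def test_exponent_zero_is_ols(self, rng):
        x = np.sort(rng.uniform(1, 50, size=8))
        r = _ratios(0.1, 0.2, x) + rng.normal(0, 0.01, size=8)
        curve = fit_calibration(x, r, weighting_exponent=0)
        slope, intercept = np.polyfit(x, r, 1)
        assert curve.slope == pytest.approx(slope, rel=1e-10)
        assert curve.intercept == pytest.approx(intercept, rel=1e-10)

    def test_weighting_helps_low_end_bias(self, rng):
        """Under multiplicative (CV) noise, 1/x² weighting back-calculates
        the lowest calibrator with less bias than OLS, in the median over
        replicated curves."""
        wins = []
        for _ in range(200):
            r = _ratios(0.02, 0.0, LEVELS) * rng.lognormal(0, 0.05, size=13)
            w = fit_calibration(LEVELS, r, weighting_exponent=2)
            o = fit_calibration(LEVELS, r, weighting_exponent=0)
            bw = abs(back_calculate(w, r[0]) / LEVELS[0] - 1)
            bo = abs(back_calculate(o, r[0]) / LEVELS[0] - 1)
            wins.append(bw - bo)
        assert np.median(wins) < 0

    def test_too_few_levels_rejected(self):
        with pytest.raises(CalibrationError):
            fit_calibration(LEVELS[:5], _ratios(1, 0, LEVELS[:5]))

    def test_zero_concentration_rejected_for_weighted(self):
        x = np.array([0.0, 1, 2, 3, 4, 5, 6])
        with pytest.raises(CalibrationError):
            fit_calibration(x, x.copy(), weighting_exponent=2)


class TestBackCalculate:
    def test_inverse_of_line(self):
        curve = CalibrationCurve("a", slope=0.02, intercept=0.0,
                                 weighting_exponent=2, weighted_r2=1.0)
        assert back_calculate(curve, 0.5) == pytest.approx(25.0)

    def test_round_trip_through_fit(self):
        r = _ratios(0.03, 0.002, LEVELS)
        curve = fit_calibration(LEVELS, r)
        np.testing.assert_allclose(back_calculate(curve, r), LEVELS, rtol=1e-10)

    def test_matches_algebraic_inversion(self, rng):
        for _ in range(20):
            slope = float(rng.uniform(0.01, 2))
            intercept = float(rng.normal(0, 0.1))
            curve = CalibrationCurve("a", slope, intercept, 2, 1.0)
            ratio = float(rng.uniform(0, 5))
            assert back_calculate(curve, ratio) == pytest.approx(
                (ratio - intercept) / slope, rel=1e-12
            )

    def test_non_positive_slope_rejected(self):
        curve = CalibrationCurve("a", slope=0.0, intercept=0.0,
                                 weighting_exponent=2, weighted_r2=1.0)
        with pytest.raises(ValueError):
            back_calculate(curve, 1.0)


class TestValidateCurve:
    def test_noise_free_all_pass(self):
        r = _ratios(0.02, 0.0, LEVELS)
        curve = fit_calibration(LEVELS, r)
        report = validate_curve(curve, LEVELS, r)
        assert report["passed"].all() and curve.accepted

    def _biased_curve(self, n_bad):
        """Perfect line with n_bad interior levels pushed to +30% bias."""
        curve = CalibrationCurve("a", slope=0.02, intercept=0.0,
                                 weighting_exponent=2, weighted_r2=1.0)
        bias = np.zeros(13)
        bias[5:5 + n_bad] = 0.3
        r = _ratios(0.02, 0.0, LEVELS, bias=bias)
        return curve, r

    def test_four_bad_levels_reject(self):
        curve, r = self._biased_curve(4)
        report = validate_curve(curve, LEVELS, r)
        assert report["passed"].sum() == 9
        assert not curve.accepted  # 9/13 = 69.2% < 75%

    def test_three_bad_levels_accept(self):
        curve, r = self._biased_curve(3)
        report = validate_curve(curve, LEVELS, r)
        assert report["passed"].sum() == 10
        assert curve.accepted  # 10/13 = 76.9% >= 75%

    def test_lloq_level_gets_20_percent(self):
        curve = CalibrationCurve("a", 0.02, 0.0, 2, 1.0)
        bias = np.zeros(13)
        bias[0] = 0.18  # within 20% at the lowest level only
        r = _ratios(0.02, 0.0, LEVELS, bias=bias)
        report = validate_curve(curve, LEVELS, r)
        assert report.loc[0, "passed"]
        bias[1] = 0.18  # same bias fails at a non-LLOQ level
        r = _ratios(0.02, 0.0, LEVELS, bias=bias)
        report = validate_curve(curve, LEVELS, r)
        assert not report.loc[1, "passed"]

    def test_acceptance_monotone_in_bias(self, rng):
        """Adding bias to any level never turns a rejected curve accepted."""
        curve = CalibrationCurve("a", 0.02, 0.0, 2, 1.0)
        for _ in range(30):
            bias = rng.normal(0, 0.2, size=13)
            r = _ratios(0.02, 0.0, LEVELS, bias=bias)
            validate_curve(curve, LEVELS, r)
            before = curve.accepted
            k = int(rng.integers(0, 13))
            worse = bias.copy()
            worse[k] += np.sign(worse[k] or 1.0) * 0.3
            r2 = _ratios(0.02, 0.0, LEVELS, bias=worse)
            validate_curve(curve, LEVELS, r2)
            if not before:
                assert not curve.accepted


class TestEstimateLimits:
    def test_noise_free_lloq_is_lowest_level(self):
        r = _ratios(0.02, 0.0, LEVELS)
        curve = fit_calibration(LEVELS, r)
        llod, lloq = estimate_limits(curve, LEVELS, r)
        assert lloq == LEVELS[0]
        assert llod < lloq

    def test_biased_lowest_level_moves_lloq_up(self):
        bias = np.zeros(13)
        bias[0] = 0.25
        r = _ratios(0.02, 0.0, LEVELS, bias=bias)
        curve = CalibrationCurve("a", 0.02, 0.0, 2, 1.0)
        _, lloq = estimate_limits(curve, LEVELS, r)
        assert lloq == LEVELS[1]

    def test_llod_linear_in_sigma(self):
        assert detection_limit(2.0, 0.5) == 2 * detection_limit(1.0, 0.5)

    def test_no_qualifying_level_flags_curve(self):
        r = _ratios(0.02, 0.0, LEVELS, bias=np.full(13, 0.5))
        curve = CalibrationCurve("a", 0.02, 0.0, 2, 1.0)
        curve.accepted = True
        _, lloq = estimate_limits(curve, LEVELS, r)
        assert np.isnan(lloq) and not curve.accepted


class TestQuantify:
    def test_noise_free_chain_is_exact(self):
        spec = synth.TargetedPanelSpec(
            n_subjects_per_group={"case": 5, "control": 5},
            ratio_cv=0.0, is_area_cv=0.0,
        )
        run = synth.generate_targeted_run(spec, 20)
        curves = calibrate_run(run)
        conc = quantify(run, curves)
        np.testing.assert_allclose(
            conc.concentrations.to_numpy(),
            run.true_concentrations.loc[conc.concentrations.index].to_numpy(),
            rtol=1e-9,
        )
        # QC recoveries exact at all four levels
        rec = run.records
        for a in spec.analytes:
            qc = rec[(rec["analyte"] == a.name) & (rec["record_type"] == "qc")]
            back = back_calculate(
                curves[a.name],
                (qc["analyte_area"] / qc["is_area"]).to_numpy(),
            )
            np.testing.assert_allclose(back, qc["nominal_conc"], rtol=1e-9)

    def test_recovery_under_noise(self):
        spec = synth.TargetedPanelSpec(
            n_subjects_per_group={"case": 30, "control": 30}, ratio_cv=0.05
        )
        run = synth.generate_targeted_run(spec, 21)
        conc = quantify(run, calibrate_run(run))
        err = np.abs(
            conc.concentrations
            / run.true_concentrations.loc[conc.concentrations.index]
            - 1
        )
        assert float(np.median(err.to_numpy())) <= 0.07

    def test_panel_is_the_four_metabolites(self):
        spec = synth.TargetedPanelSpec(n_subjects_per_group={"case": 2, "control": 2})
        run = synth.generate_targeted_run(spec, 22)
        conc = quantify(run, calibrate_run(run))
        assert conc.analytes == ["inosine", "uridine", "phenylalanine", "threonine"]

    def test_rejected_curve_blocks_quantification(self):
        spec = synth.TargetedPanelSpec(n_subjects_per_group={"case": 2, "control": 2})
        run = synth.generate_targeted_run(spec, 23)
        curves = calibrate_run(run)
        curves["inosine"].accepted = False
        with pytest.raises(CalibrationError):
            quantify(run, curves)

    def test_missing_is_leaves_cell_missing(self):
        spec = synth.TargetedPanelSpec(
            n_subjects_per_group={"case": 2, "control": 2}, ratio_cv=0.0,
            is_area_cv=0.0,
        )
        run = synth.generate_targeted_run(spec, 24)
        rec = run.records
        idx = rec[(rec["record_type"] == "subject")
                  & (rec["analyte"] == "uridine")].index[0]
        sid = rec.loc[idx, "sample_id"]
        run.records.loc[idx, "is_area"] = 0.0
        conc = quantify(run, calibrate_run(run))
        assert np.isnan(conc.concentrations.loc[sid, "uridine"])
        assert conc.concentrations.drop(index=sid).notna().all().all()

    def test_below_lloq_flagged_not_censored(self):
        spec = synth.TargetedPanelSpec(
            n_subjects_per_group={"case": 3, "control": 3}, ratio_cv=0.0,
            is_area_cv=0.0,
        )
        run = synth.generate_targeted_run(spec, 25)
        curves = calibrate_run(run)
        curves["inosine"].lloq = 1e9  # force everything below LLOQ
        conc = quantify(run, curves)
        assert conc.below_lloq["inosine"].all()
        assert conc.concentrations["inosine"].notna().all()
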