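"""Bias quantification: regression slopes, percent bias, agreement, correction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from petdosim import (
    BiasReport,
    FitResult,
    MissingOrganError,
    ValidationError,
    apply_correction,
    bias_report,
    bland_altman,
    compare_reconstructions,
    correction_factor,
    fit_prediction_line,
    identity_line_test,
    lli_sensitivity,
    mean_percent_bias,
)


class TestFitPredictionLine:
    def test_identity_data(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        fit = fit_prediction_line(t, t)
        assert fit.slope == pytest.approx(1.0, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert mean_percent_bias(fit.slope) == pytest.approx(0.0, abs=1e-9)

    def test_noiseless_double(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        fit = fit_prediction_line(2 * t, t)
        assert fit.slope == pytest.approx(2.0, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_known_slope_recovered_within_own_ci(self):
        rng = np.random.default_rng(19)
        t = np.linspace(0.01, 0.05, 10)
        p = 0.6 * t + rng.normal(0, 0.002, 10)
        fit = fit_prediction_line(p, t)
        assert fit.ci_low <= 0.6 <= fit.ci_high

    def test_series_inputs_matched_by_label(self):
        t = pd.Series({"kidneys": 1.0, "liver": 2.0, "brain": 3.0})
        p = pd.Series({"brain": 6.0, "kidneys": 2.0, "liver": 4.0})
        fit = fit_prediction_line(p, t)
        assert fit.slope == pytest.approx(2.0, abs=1e-12)

    def test_two_point_through_origin_closed_form(self):
        # through-origin OLS slope = Σxy / Σx²
        x = np.array([1.0, 3.0])
        y = np.array([2.5, 5.0])
        fit = fit_prediction_line(
            np.r_[y, y], np.r_[x, x], through_origin=True
        )
        assert fit.slope == pytest.approx((x @ y) / (x @ x), rel=1e-12)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValidationError, match="3 matched"):
            fit_prediction_line([1.0, 2.0], [1.0, 2.0])

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError, match="variance"):
            fit_prediction_line([1.0, 2.0, 3.0], [2.0, 2.0, 2.0])


class TestMeanPercentBias:
    @pytest.mark.parametrize(
        "slope, bias",
        [(2.111, 111.1), (0.4166, 58.34), (1.0, 0.0), (0.5956, 40.44)],
    )
    def test_published_slope_arithmetic(self, slope, bias):
        assert mean_percent_bias(slope) == pytest.approx(bias, abs=1e-9)

    @settings(max_examples=50, deadline=None)
    @given(x=st.floats(min_value=0.0, max_value=5.0))
    def test_symmetry_about_unit_slope(self, x):
        assert mean_percent_bias(1 + x) == pytest.approx(
            mean_percent_bias(1 - x), rel=1e-12, abs=1e-12
        )

    def test_non_finite_slope_rejected(self):
        with pytest.raises(ValidationError):
            mean_percent_bias(float("nan"))


class TestIdentityLineTest:
    def test_ci_excluding_one_differs(self):
        assert identity_line_test(2.111, (1.898, 2.323)) is True

    def test_ci_containing_one_does_not_differ(self):
        assert identity_line_test(1.019, (0.7037, 1.335)) is False

    def test_degenerate_ci_at_one_inclusive(self):
        assert identity_line_test(1.0, (1.0, 1.0)) is False

    def test_slope_outside_its_ci_rejected(self):
        with pytest.raises(ValidationError):
            identity_line_test(5.0, (1.0, 2.0))


class TestBlandAltman:
    def test_identical_arrays(self):
        x = np.array([1.0, 2.0, 3.0])
        s = bland_altman(x, x)
        assert s.mean_diff == 0.0
        assert s.loa == (0.0, 0.0)

    def test_constant_offset(self):
        t = np.arange(5, dtype=float)
        s = bland_altman(t + 1.0, t)
        assert s.mean_diff == pytest.approx(1.0)
        assert s.sd_diff == pytest.approx(0.0, abs=1e-15)

    def test_matches_hand_recomputation(self):
        rng = np.random.default_rng(8)
        t = rng.uniform(0.01, 0.06, 9)
        p = t * 0.7 + rng.normal(0, 0.004, 9)
        s = bland_altman(p, t)
        d = p - t  # independent spreadsheet-style recomputation
        assert s.mean_diff == pytest.approx(d.mean(), rel=1e-12)
        assert s.sd_diff == pytest.approx(d.std(ddof=1), rel=1e-12)
        assert s.loa_low == pytest.approx(d.mean() - 1.96 * d.std(ddof=1), rel=1e-12)

    def test_loa_contain_95pct_of_normal_differences(self):
        rng = np.random.default_rng(123)
        t = rng.uniform(1, 2, 10_000)
        p = t + rng.normal(0, 0.1, 10_000)
        s = bland_altman(p, t)
        inside = np.mean((s.diffs >= s.loa_low) & (s.diffs <= s.loa_high))
        assert 0.94 <= inside <= 0.96

    def test_single_pair_rejected(self):
        with pytest.raises(ValidationError):
            bland_altman([1.0], [1.0])


class TestLLISensitivity:
    def _pairs(self, lli_pred=None):
        t = pd.Series(
            {"kidneys": 0.05, "liver": 0.02, "lli_wall": 0.03,
             "brain": 0.01, "heart": 0.015}
        )
        p = 0.6 * t
        if lli_pred is not None:
            p["lli_wall"] = lli_pred
        return p, t

    def test_lli_on_the_line_gives_unit_ratio(self):
        p, t = self._pairs()
        s = lli_sensitivity(p, t)
        assert s.improvement_ratio == pytest.approx(1.0, rel=1e-9)

    def test_lli_outlier_inflates_bias(self):
        # LLI predicted far too low: slope drops below 0.6, bias inflates
        p, t = self._pairs(lli_pred=0.001)
        s = lli_sensitivity(p, t)
        assert s.bias_without == pytest.approx(40.0, rel=1e-9)
        assert s.bias_with > s.bias_without
        assert s.improvement_ratio > 1.0

    def test_missing_lli_is_an_error(self):
        t = pd.Series({"kidneys": 0.05, "liver": 0.02, "brain": 0.01})
        with pytest.raises(MissingOrganError):
            lli_sensitivity(0.6 * t, t)

    def test_removal_leaving_too_few_pairs_is_an_error(self):
        t = pd.Series({"kidneys": 0.05, "liver": 0.02, "lli_wall": 0.03})
        with pytest.raises(ValidationError, match="3 matched"):
            lli_sensitivity(0.6 * t, t)


def _report(slope, model="adult_male, normalised, FBP"):
    return BiasReport(
        model=model,
        fit=FitResult(slope, 0.02, 0.85, slope - 0.05, slope + 0.05, 0.0, 9),
    )


class TestCorrectionFactor:
    def test_normalised_fbp_family_mean_and_range(self):
        reports = [_report(s) for s in (0.5956, 0.7793, 0.4166, 0.5404)]
        cf = correction_factor(reports)
        assert cf.mean_percent == pytest.approx(41.7025, abs=1e-9)
        assert cf.rounded_percent == 42
        assert cf.range_percent[0] == pytest.approx(22.07, abs=1e-9)
        assert cf.range_percent[1] == pytest.approx(58.34, abs=1e-9)

    def test_single_report(self):
        cf = correction_factor([_report(0.6)])
        assert cf.mean_percent == pytest.approx(40.0)
        assert cf.range_percent == (40.0, 40.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            correction_factor([])

    def test_mixed_model_types_warn(self):
        with pytest.warns(UserWarning, match="normalised-FBP"):
            correction_factor(
                [_report(0.6), _report(2.0, model="adult_male, non-normalised, FBP")]
            )


class TestApplyCorrection:
    def test_unit_slope_is_identity(self):
        p = pd.Series({"kidneys": 0.5})
        assert apply_correction(p, slope=1.0)["kidneys"] == 0.5

    def test_slope_correction_restores_identity(self):
        assert apply_correction(
            pd.Series({"kidneys": 0.5956}), slope=0.5956
        )["kidneys"] == pytest.approx(1.0, rel=1e-12)

    def test_simplified_mode(self):
        out = apply_correction(pd.Series({"kidneys": 0.58}), bias_percent=42.0)
        assert out["kidneys"] == pytest.approx(1.0, rel=1e-12)

    def test_refit_after_correction_has_unit_slope(self):
        t = pd.Series(np.linspace(0.01, 0.05, 6),
                      index=[f"o{i}" for i in range(6)])
        p = 0.62 * t
        fit = fit_prediction_line(p, t)
        refit = fit_prediction_line(apply_correction(p, slope=fit.slope), t)
        assert refit.slope == pytest.approx(1.0, abs=1e-9)

    def test_invalid_arguments_rejected(self):
        p = pd.Series({"kidneys": 0.5})
        with pytest.raises(ValidationError):
            apply_correction(p, slope=-1.0)
        with pytest.raises(ValidationError):
            apply_correction(p, bias_percent=120.0)
        with pytest.raises(ValidationError):
            apply_correction(p, slope=1.0, bias_percent=10.0)
        with pytest.raises(ValidationError):
            apply_correction(p)


class TestCompareReconstructions:
    def test_identical_taus(self):
        tau = np.array([0.1, 0.4, 0.8, 1.2])
        cmp = compare_reconstructions(tau, tau)
        assert cmp.fit.slope == pytest.approx(1.0, abs=1e-12)
        assert cmp.mean_ratio == pytest.approx(1.0, rel=1e-12)

    def test_exact_ratio_recovered(self):
        tau = np.array([0.1, 0.4, 0.8, 1.2])
        cmp = compare_reconstructions(tau, 1.6 * tau)
        assert cmp.fit.slope == pytest.approx(1.6, abs=1e-12)
        assert cmp.fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert cmp.mean_ratio == pytest.approx(1.6, rel=1e-12)

    def test_zero_fbp_tau_rejected(self):
        with pytest.raises(ValidationError):
            compare_reconstructions([0.0, 1.0, 2.0], [0.1, 1.6, 3.2])

    def test_seeded_cohort_ci_contains_generating_ratio(self):
        from petdosim import default_kinetic_spec, generate_scan, residence_times

        spec = default_kinetic_spec(noise_cv=0.08)
        fbp_taus, itr_taus = [], []
        for s in range(6):
            fbp, itr = generate_scan(spec, seed=700 + s)
            rf, ri = residence_times(fbp), residence_times(itr)
            for organ in rf.organs:
                fbp_taus.append(rf.organs[organ])
                itr_taus.append(ri.organs[organ])
        cmp = compare_reconstructions(fbp_taus, itr_taus)
        assert cmp.fit.ci_low <= 1.6 <= cmp.fit.ci_high


class TestBiasReportInvariants:
    def test_report_fields_consistent(self):
        t = pd.Series(np.linspace(0.01, 0.05, 8), index=[f"o{i}" for i in range(8)])
        rng = np.random.default_rng(4)
        p = 0.6 * t * rng.lognormal(0, 0.1, 8)
        rep = bias_report(p, t, model="adult_male, normalised, FBP")
        assert rep.fit.ci_low <= rep.slope <= rep.fit.ci_high
        assert 0.0 <= rep.fit.r2 <= 1.0
        assert rep.mean_percent_bias == pytest.approx(
            abs(1 - rep.slope) * 100, rel=1e-15
        )
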