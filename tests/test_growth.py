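"""Growth-rate scoring: mu, mu/mu.max, sigmoid fits, AUC, GI75, caspase."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from chemscreen import growth
from chemscreen.growth import (
    CalibrationError,
    SigmoidFit,
    classify_sensitivity,
    compute_auc,
    compute_gi75,
    compute_mu,
    fit_atp_standard,
    fit_sigmoid,
    four_param_logistic,
    mu_ratio,
    normalize_caspase,
    normalize_readout,
    WellMeasurement,
)


class TestATPStandard:
    @pytest.mark.parametrize(
        "points,slope,intercept",
        [
            ([(0, 0), (1000, 1000)], 1.0, 0.0),
            ([(0, 0), (1000, 2000)], 2.0, 0.0),
            ([(0, 100), (500, 1100), (1000, 2100)], 2.0, 100.0),
        ],
    )
    def test_linear_calibration(self, points, slope, intercept):
        curve = fit_atp_standard(points)
        assert curve.slope == pytest.approx(slope)
        assert curve.intercept == pytest.approx(intercept)

    @pytest.mark.parametrize("points", [[(500, 700)], [(0, 5), (100, 5)], []])
    def test_degenerate_points_rejected(self, points):
        with pytest.raises(CalibrationError):
            fit_atp_standard(points)

    def test_normalize_readout_inverts_calibration(self):
        curve = fit_atp_standard([(0, 0), (1000, 2000)])
        wells = [WellMeasurement("A1", "sample", 96, 2000.0)]
        assert normalize_readout(wells, curve)[0].signal == pytest.approx(1000.0)

    def test_identity_curve_leaves_signals_unchanged(self):
        curve = fit_atp_standard([(0, 0), (1000, 1000)])
        wells = [WellMeasurement("A1", "sample", 0, 123.4)]
        assert normalize_readout(wells, curve)[0].signal == pytest.approx(123.4)

    def test_signal_below_intercept_clamps_to_zero_with_warning(self):
        curve = fit_atp_standard([(0, 100), (1000, 2100)])
        wells = [WellMeasurement("A1", "blank", 0, 50.0)]
        with pytest.warns(UserWarning, match="clamped"):
            out = normalize_readout(wells, curve)
        assert out[0].signal == 0.0


class TestComputeMu:
    def test_doubling_over_96h(self):
        assert compute_mu(1000, 2000, 0, 96) == pytest.approx(np.log(2) / 96)

    def test_no_growth_gives_zero(self):
        assert compute_mu(1000, 1000, 0, 96) == 0.0

    def test_shrinking_culture_gives_negative_mu(self):
        assert compute_mu(1000, 400, 0, 96) < 0

    def test_t0_at_blank_is_input_error(self):
        with pytest.raises(ValueError):
            compute_mu(100, 500, 100, 96)

    def test_tend_below_blank_floors_with_warning(self):
        with pytest.warns(UserWarning, match="floored"):
            mu = compute_mu(1000, 5, 10, 96, floor_ratio=0.01)
        assert mu == pytest.approx(np.log(0.01) / 96)

    @given(
        c=st.floats(min_value=1e-3, max_value=1e6),
        tend=st.floats(min_value=200, max_value=5000),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_scale_invariance(self, c, tend):
        base = compute_mu(1000, tend, 100, 96)
        scaled = compute_mu(1000 * c, tend * c, 100 * c, 96)
        assert scaled == pytest.approx(base, rel=1e-9)


class TestMuRatio:
    def test_drug_equal_to_controls_means_no_effect(self):
        assert mu_ratio(0.01, [0.01, 0.01, 0.01]).ratio == pytest.approx(1.0)

    def test_zero_growth_gives_zero_ratio(self):
        assert mu_ratio(0.0, [0.01, 0.02]).ratio == 0.0

    def test_negative_mu_gives_cytotoxic_ratio(self):
        assert mu_ratio(-0.005, [0.01]).ratio < 0

    def test_no_growth_in_controls_is_error(self):
        with pytest.raises(ValueError):
            mu_ratio(0.01, [0.0, -0.01])


class TestFitSigmoid:
    def test_parameter_recovery_noiseless(self):
        doses = np.logspace(-3, 1, 10)
        true = (0.0, 1.0, -1.0, -1.0)  # bottom, top, log_ec50, hill
        ratios = four_param_logistic(np.log10(doses), *true)
        fit = fit_sigmoid(doses, ratios)
        assert fit.converged
        for got, want in zip((fit.bottom, fit.top, fit.log_ec50, fit.hill), true):
            assert got == pytest.approx(want, abs=1e-6)

    def test_flat_response_fits_constant_one(self):
        doses = np.logspace(-3, 0, 8)
        fit = fit_sigmoid(doses, np.ones_like(doses))
        grid = np.linspace(-3, 0, 50)
        assert np.allclose(fit.predict(grid), 1.0, atol=1e-6)

    def test_too_few_distinct_doses_rejected(self):
        with pytest.raises(ValueError):
            fit_sigmoid([0.1, 1.0, 10.0], [1.0, 0.5, 0.0])

    def test_recovery_error_shrinks_with_noise(self):
        doses = np.repeat(np.logspace(-3, 1, 10), 3)
        clean = four_param_logistic(np.log10(doses), 0.0, 1.0, -1.0, -1.0)
        rng = np.random.default_rng(7)
        errs = []
        for sigma in (0.1, 0.01, 0.001):
            fit = fit_sigmoid(doses, clean + rng.normal(0, sigma, clean.shape))
            errs.append(abs(fit.log_ec50 - (-1.0)))
        assert errs[2] < errs[0]
        assert errs[2] < 1e-2


class TestAUC:
    def test_constant_one_curve_integrates_to_range_width(self):
        fit = SigmoidFit(1.0, 1.0, 0.0, -1.0, True, 0.0)
        width = np.log10(3.0) - np.log10(1e-3)  # 1 nM -> 3 uM
        assert compute_auc(fit, (-3.0, np.log10(3.0))) == pytest.approx(width, abs=1e-6)
        assert width == pytest.approx(3.477, abs=1e-3)

    def test_zero_curve_integrates_to_zero(self):
        fit = SigmoidFit(0.0, 0.0, 0.0, -1.0, True, 0.0)
        assert compute_auc(fit, (-3.0, 1.0)) == pytest.approx(0.0, abs=1e-12)

    def test_steep_step_matches_quadrature_oracle(self):
        # near-step from 1 to 0 at mid-range: AUC ~ half the width
        fit = SigmoidFit(0.0, 1.0, -1.0, -15.0, True, 0.0)
        oracle, _ = quad(
            lambda x: four_param_logistic(x, 0.0, 1.0, -1.0, -15.0), -3, 1, limit=500
        )
        auc = compute_auc(fit, (-3.0, 1.0))
        assert auc == pytest.approx(oracle, abs=0.01)
        assert auc == pytest.approx(2.0, abs=0.01)

    def test_dominated_curve_has_smaller_auc(self):
        hi = SigmoidFit(0.2, 1.0, -1.0, -1.0, True, 0.0)
        lo = SigmoidFit(0.0, 0.8, -1.0, -1.0, True, 0.0)
        assert compute_auc(lo, (-3, 1)) <= compute_auc(hi, (-3, 1))

    def test_fallback_interpolation_used_when_not_converged(self):
        fit = SigmoidFit(
            0, 1, 0, -1, converged=False, residual_rms=float("nan"),
            log_doses=np.array([-2.0, 0.0]), mean_ratios=np.array([1.0, 0.0]),
        )
        assert compute_auc(fit, (-2.0, 0.0)) == pytest.approx(1.0, abs=1e-6)


class TestClassification:
    @pytest.mark.parametrize(
        "auc,category",
        [
            (1.5, "sensitive"),
            (5.0, "moderate"),
            (9.5, "insensitive"),
            (2.0, "moderate"),  # boundary values land in the moderate band
            (9.0, "moderate"),
        ],
    )
    def test_thresholds(self, auc, category):
        assert classify_sensitivity(auc).category == category

    def test_panel_counts_match_brute_force(self, rng):
        aucs = rng.uniform(0, 12, size=500)
        counts = growth.classify_panel(aucs)
        assert counts["sensitive"] == int(np.sum(aucs < 2.0))
        assert counts["insensitive"] == int(np.sum(aucs > 9.0))
        assert sum(counts.values()) == 500


class TestGI75:
    def test_log_linear_crossing_at_tested_dose(self):
        res = compute_gi75([0.01, 1.0], [1.0, 0.25])
        assert res.gi75 == pytest.approx(1.0)
        assert res.sensitive_call

    def test_crossing_between_doses_hits_quarter_viability(self):
        conc = np.logspace(-2, 1, 7)
        frac = np.clip(0.55 - 0.35 * np.log10(conc), 0.01, 1.0)
        res = compute_gi75(conc, frac)
        # oracle: fraction interpolated at gi75 equals 0.25
        interp = np.interp(np.log10(res.gi75), np.log10(conc), frac)
        assert interp == pytest.approx(0.25, abs=1e-9)

    def test_never_crossing_is_undefined(self):
        res = compute_gi75([0.01, 0.1, 1.0], [1.0, 0.9, 0.8])
        assert res.gi75 is None and not res.sensitive_call

    def test_cutoff_controls_sensitive_call(self):
        res = compute_gi75([1.0, 10.0], [1.0, 0.1], cutoff_um=2.0)
        assert res.gi75 > 2.0 and not res.sensitive_call

    def test_unordered_concentrations_are_sorted(self):
        a = compute_gi75([1.0, 0.01], [0.25, 1.0])
        b = compute_gi75([0.01, 1.0], [1.0, 0.25])
        assert a.gi75 == pytest.approx(b.gi75)


class TestCaspase:
    def test_fold_induction(self):
        assert normalize_caspase(2000, 100, 1000, 100) == pytest.approx(1900 / 900)

    def test_signal_equal_to_dmso_is_unity(self):
        assert normalize_caspase(1000, 100, 1000, 100) == pytest.approx(1.0)

    def test_signal_equal_to_background_is_zero(self):
        assert normalize_caspase(100, 100, 1000, 100) == 0.0

    def test_dead_control_is_error(self):
        with pytest.raises(ValueError):
            normalize_caspase(2000, 100, 100, 100)
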