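import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nircal.chemometrics import fit_calibration
from nircal.preprocess import PreprocessSpec
from nircal.validation import (
    accuracy_profile,
    is_compliant,
    linearity_profile,
    tolerance_interval,
    trueness,
    validate_model,
    validate_predictions,
    variance_components,
)


class TestTrueness:
    def test_central_level_worked_example(self):
        # mean 12.60 at nominal 12.50 -> recovery 100.80 %
        _, recovery, rel_bias = trueness(np.array([12.60]), 12.50)
        assert recovery == pytest.approx(100.80, abs=1e-10)
        assert rel_bias == pytest.approx(0.80, abs=1e-10)

    def test_exact_predictions(self):
        _, recovery, rel_bias = trueness(np.full(12, 10.0), 10.0)
        assert recovery == 100.0
        assert rel_bias == 0.0

    def test_ten_percent_high(self):
        _, recovery, rel_bias = trueness(np.array([11.0]), 10.0)
        assert recovery == pytest.approx(110.0)
        assert rel_bias == pytest.approx(10.0)

    def test_nonpositive_nominal_rejected(self):
        with pytest.raises(ValueError):
            trueness(np.array([1.0]), 0.0)


class TestVarianceComponents:
    def test_identical_series(self):
        """Same values in every series: between-series component is zero,
        within-series variance is the pooled one."""
        row = np.array([9.0, 11.0, 10.0, 10.0])
        M = np.vstack([row, row, row])
        vc = variance_components(M)
        assert vc.s_b2 == 0.0
        assert vc.s_w2 == pytest.approx(np.var(row, ddof=1), abs=1e-12)

    def test_hand_anova_toy(self):
        """(9,11) vs (19,21): MS_W = 2, MS_B = 200 -> s_b2 = 99, hand-checked
        from the raw sums of squares."""
        M = np.array([[9.0, 11.0], [19.0, 21.0]])
        # oracle via direct sums of squares
        grand = M.mean()
        ss_b = 2 * ((M.mean(axis=1) - grand) ** 2).sum()
        ss_w = ((M - M.mean(axis=1, keepdims=True)) ** 2).sum()
        vc = variance_components(M)
        assert vc.grand_mean == 15.0
        assert vc.ms_w == pytest.approx(ss_w / 2) == pytest.approx(2.0)
        assert vc.ms_b == pytest.approx(ss_b / 1)
        assert vc.s_w2 == pytest.approx(2.0)
        assert vc.s_b2 == pytest.approx((vc.ms_b - 2.0) / 2)
        assert vc.s_ip2 == pytest.approx(vc.s_w2 + vc.s_b2)

    def test_monte_carlo_recovery(self):
        """p=3, n=4, true (sigma_w^2, sigma_b^2) = (1, 0.25): mean of the
        unclipped estimates lands within 10 % of truth over 2000 reps."""
        rng = np.random.default_rng(31)
        p, n = 3, 4
        w_hat, b_hat = [], []
        for _ in range(2000):
            M = 10 + rng.normal(0, 0.5, (p, 1)) + rng.normal(0, 1.0, (p, n))
            vc = variance_components(M)
            w_hat.append(vc.s_w2)
            b_hat.append(vc.s_b2_raw)
        assert abs(np.mean(w_hat) - 1.0) < 0.10
        assert abs(np.mean(b_hat) - 0.25) < 0.025

    def test_zero_between_series_often_clips_to_zero(self):
        """With no true between-series effect the clipped estimate is 0 in
        at least half of the simulations."""
        rng = np.random.default_rng(32)
        clipped = sum(
            variance_components(rng.normal(10, 1, (3, 4))).s_b2 == 0.0
            for _ in range(500)
        )
        assert clipped >= 250

    def test_shape_and_balance_requirements(self):
        with pytest.raises(ValueError):
            variance_components(np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            variance_components(np.ones((1, 4)))
        with pytest.raises(ValueError):
            variance_components(np.array([[1.0, np.nan], [2.0, 3.0]]))


class TestToleranceInterval:
    def test_symmetric_and_contains_bias(self):
        lo, hi = tolerance_interval(1.3, 0.02, 0.01, 3, 4, 12.5)
        assert lo < 1.3 < hi
        assert (1.3 - lo) == pytest.approx(hi - 1.3, abs=1e-12)

    def test_degenerate_point_interval(self):
        assert tolerance_interval(0.7, 0.0, 0.0, 3, 4, 10.0) == (0.7, 0.7)

    def test_zero_between_series_reduction(self):
        """s_b2 = 0 reduces to bias +/- t_nu * sqrt(1 + 1/(p n)) * RSD_IP
        with nu evaluated at R = 0 (algebraic limit of the general rule)."""
        p, n, nominal, s_w2 = 3, 4, 12.5, 0.04
        lo, hi = tolerance_interval(0.0, s_w2, 0.0, p, n, nominal)
        nu = 1.0 / (1.0 / n**2 / (p - 1) + (1 - 1 / n) / (p * n))
        t = stats.t.ppf(0.975, nu)
        expected = t * np.sqrt(1 + 1 / (p * n)) * 100 * np.sqrt(s_w2) / nominal
        assert hi == pytest.approx(expected, abs=1e-10)
        assert lo == pytest.approx(-expected, abs=1e-10)

    def test_beta_monotone(self):
        lo95, hi95 = tolerance_interval(0.0, 0.02, 0.01, 3, 4, 12.5, beta=0.95)
        lo99, hi99 = tolerance_interval(0.0, 0.02, 0.01, 3, 4, 12.5, beta=0.99)
        assert lo99 < lo95 and hi99 > hi95

    def test_coverage_monte_carlo(self):
        """Expected coverage of a future single result is ~beta (reduced-size
        version of the full acceptance simulation)."""
        rng = np.random.default_rng(33)
        p, n, nominal = 3, 4, 12.5
        sb, sw = 0.05, 0.12
        inside = 0
        n_sim = 1500
        for _ in range(n_sim):
            M = 12.6 + rng.normal(0, sb, (p, 1)) + rng.normal(0, sw, (p, n))
            vc = variance_components(M)
            rel_bias = 100 * (M.mean() - nominal) / nominal
            lo, hi = tolerance_interval(rel_bias, vc.s_w2, vc.s_b2, p, n, nominal)
            future = 12.6 + rng.normal(0, sb) + rng.normal(0, sw)
            inside += lo <= 100 * (future - nominal) / nominal <= hi
        assert inside / n_sim == pytest.approx(0.95, abs=0.03)

    def test_bad_beta_rejected(self):
        with pytest.raises(ValueError):
            tolerance_interval(0.0, 0.1, 0.0, 3, 4, 10.0, beta=1.0)


class TestComplianceRule:
    def test_printed_profile_row_compliant(self):
        # limits (-3.022, +3.557) against +/-5 -> compliant
        assert is_compliant(-3.022, 3.557, -5, 5)

    def test_excursion_non_compliant(self):
        assert not is_compliant(-6.0, 2.0, -5, 5)

    def test_monotone_in_acceptance(self):
        """Widening the acceptance limits never breaks compliance."""
        rng = np.random.default_rng(34)
        for _ in range(200):
            lo, hi = sorted(rng.uniform(-8, 8, 2))
            a = rng.uniform(0.5, 10)
            if is_compliant(lo, hi, -a, a):
                assert is_compliant(lo, hi, -(a + 1), a + 1)


def _predictions_frame(rng, levels=(10.0, 12.5, 15.0), p=3, n=4,
                       bias=0.0, sw=0.1, sb=0.05):
    rows = []
    for nominal in levels:
        for s in range(1, p + 1):
            offset = rng.normal(0, sb)
            for _ in range(n):
                rows.append({
                    "nominal_pct_ww": nominal,
                    "series": s,
                    "prediction": nominal + bias + offset + rng.normal(0, sw),
                })
    return pd.DataFrame(rows)


class TestAccuracyProfile:
    def test_level_structure(self):
        frame = _predictions_frame(np.random.default_rng(35))
        profile = accuracy_profile(frame)
        assert [lv.nominal for lv in profile] == [10.0, 12.5, 15.0]
        for lv in profile:
            assert lv.p == 3 and lv.n == 4
            assert lv.rel_tol_lower <= lv.relative_bias <= lv.rel_tol_upper
            assert lv.s_ip2 >= lv.s_w2
            assert lv.abs_tol_lower == pytest.approx(
                lv.nominal * (1 + lv.rel_tol_lower / 100), abs=1e-10
            )
            assert lv.abs_tol_upper == pytest.approx(
                lv.nominal * (1 + lv.rel_tol_upper / 100), abs=1e-10
            )

    def test_unbalanced_rejected(self):
        frame = _predictions_frame(np.random.default_rng(36))
        with pytest.raises(ValueError, match="unbalanced"):
            accuracy_profile(frame.iloc[:-1])

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            accuracy_profile(pd.DataFrame({"prediction": [1.0]}))

    def test_large_bias_non_compliant(self):
        frame = _predictions_frame(np.random.default_rng(37), bias=1.0)
        profile = accuracy_profile(frame, acceptance_rel=5.0)
        # 10 % bias at the low level blows through +/-5 %
        low = [lv for lv in profile if lv.nominal == 10.0][0]
        assert low.relative_bias == pytest.approx(10.0, abs=2.0)
        assert not low.compliant

    def test_zero_noise_pipeline_compliant(self, noiseless_data):
        """Noiseless end-to-end run: recoveries pinned at 100 %, degenerate
        tolerance intervals within +/-0.1 %, every level compliant."""
        cal, val = noiseless_data
        model = fit_calibration(
            cal, PreprocessSpec(method="smoothing_savitzky_golay"), "pls",
            max_factors=4, h_selected=2,
        )
        report = validate_model(model, val)
        assert report.all_compliant
        for lv in report.levels:
            assert lv.recovery == pytest.approx(100.0, abs=0.1)
            assert abs(lv.rel_tol_lower) < 0.1 and abs(lv.rel_tol_upper) < 0.1


class TestLinearityProfile:
    def test_perfect_predictions(self):
        nominal = np.repeat([10.0, 12.5, 15.0], 12)
        fit = linearity_profile(nominal, nominal)
        assert fit.slope == pytest.approx(1.0, abs=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-10)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_acceptance_limits_at_level_ten(self):
        nominal = np.repeat([10.0, 15.0], 4)
        fit = linearity_profile(nominal, nominal, acceptance_rel=5.0)
        assert fit.acceptance_lower[0] == pytest.approx(9.500)
        assert fit.acceptance_upper[0] == pytest.approx(10.500)

    def test_ten_percent_slope_non_compliant(self):
        rng = np.random.default_rng(38)
        frame = _predictions_frame(rng, sw=0.02, sb=0.0)
        frame["prediction"] = 1.1 * frame["nominal_pct_ww"] + (
            frame["prediction"] - frame["nominal_pct_ww"]
        )
        report = validate_predictions(frame, acceptance_rel=5.0)
        assert report.linearity.slope == pytest.approx(1.1, abs=0.02)
        assert report.linearity.r2 > 0.99
        assert not any(report.linearity.compliant)
        assert not report.all_compliant

    def test_single_level_rejected(self):
        with pytest.raises(ValueError, match="levels"):
            linearity_profile(np.ones(4), np.full(4, 10.0))


class TestValidationReport:
    def test_frames_and_summary(self):
        frame = _predictions_frame(np.random.default_rng(39))
        report = validate_predictions(frame)
        levels = report.levels_frame()
        assert len(levels) == 3
        assert {"recovery", "rsd_repeatability", "rel_tol_lower", "compliant"} <= set(
            levels.columns
        )
        assert len(report.linearity_frame()) == 3
        assert "slope" in report.summary()

    def test_no_between_series_effect_rsd_gap_vanishes(self):
        """sigma_b = 0: intermediate-precision RSD exceeds repeatability RSD
        only through clipping noise; the mean gap stays tiny."""
        rng = np.random.default_rng(40)
        gaps = []
        for _ in range(500):
            M = 12.5 + rng.normal(0, 0.125, (3, 4))  # ~1 % RSD, no series effect
            vc = variance_components(M)
            gaps.append(
                100 * (np.sqrt(vc.s_ip2) - np.sqrt(vc.s_w2)) / vc.grand_mean
            )
        assert np.mean(gaps) < 0.1
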