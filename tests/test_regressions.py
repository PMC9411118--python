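"""Log-log OLS, SMA, separate-slopes and interaction machinery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from leafphos import (PClassing, class_contrast_at, fold_change, linear_ols,
                      log_ols, np_interaction_model, separate_slopes_test,
                      sma_fit, threshold_sweep)
from leafphos.regressions import RegressionResult
from leafphos.synthetic import gen_classed_traits, residual_sd_for_r2


def _line_fit(slope, intercept):
    return RegressionResult(slope=slope, intercept=intercept, r2=1.0, F=0.0,
                            p=0.0, df_den=0, n=0)


class TestLogOls:
    def test_perfect_power_law(self):
        x = np.array([0.5, 1.0, 2.0, 4.0, 9.0])
        y = 2.0 * np.sqrt(x)
        r = log_ols(y, x)
        assert r.slope == pytest.approx(0.5, abs=1e-12)
        assert r.intercept == pytest.approx(np.log(2.0), abs=1e-12)
        assert r.r2 == pytest.approx(1.0, abs=1e-12)
        assert r.df_den == len(x) - 2

    def test_constant_response_gives_zero_slope(self):
        r = log_ols(np.full(6, 3.0), np.array([1, 2, 3, 4, 5, 6.0]))
        assert r.slope == pytest.approx(0.0, abs=1e-12)
        assert r.r2 == 0.0

    def test_slope_recovery_at_dataset_scale(self):
        # generating truth: ln V = 3.783 + 0.751 ln N + noise, n = 446
        rng = np.random.default_rng(7)
        lnN = rng.normal(np.log(20.0), 0.30, 446)
        fitted = 3.783 + 0.751 * lnN
        sd = residual_sd_for_r2(fitted, 0.30)
        y = np.exp(fitted + rng.normal(0.0, sd, 446))
        r = log_ols(y, np.exp(lnN))
        se = abs(r.slope) / np.sqrt(r.F)  # SE of slope from the F statistic
        assert abs(r.slope - 0.751) < 2 * se

    def test_nonpositive_values_name_rows(self):
        y = np.array([1.0, -2.0, 3.0])
        with pytest.raises(ValueError, match=r"rows: \[1\]"):
            log_ols(y, np.array([1.0, 2.0, 3.0]))


class TestSma:
    def test_sd_ratio_definition(self):
        rng = np.random.default_rng(0)
        lnx = rng.normal(0.0, 0.4, 200)
        lny = 0.3 + 2.0 * lnx + rng.normal(0.0, 1e-9, 200)
        # sd(ln y) = 2 sd(ln x) and r > 0 -> slope 2
        r = sma_fit(np.exp(lny), np.exp(lnx))
        assert r.slope == pytest.approx(2.0, rel=1e-6)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_sma_ols_identity(self, seed):
        rng = np.random.default_rng(seed)
        x = np.exp(rng.normal(0.0, 0.5, 80))
        y = np.exp(0.2 + 0.7 * np.log(x) + rng.normal(0.0, 0.3, 80))
        ols, sma = log_ols(y, x), sma_fit(y, x)
        r = np.sign(ols.slope) * np.sqrt(ols.r2)
        assert abs(sma.slope) == pytest.approx(abs(ols.slope) / abs(r), rel=1e-10)
        assert abs(sma.slope) >= abs(ols.slope)

    def test_equal_on_perfectly_correlated_data(self):
        x = np.array([1.0, 2.0, 4.0, 8.0])
        y = 3.0 * x ** 1.3
        assert sma_fit(y, x).slope == pytest.approx(log_ols(y, x).slope, rel=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            sma_fit(np.array([2.0, 2.0, 2.0]), np.array([1.0, 2.0, 3.0]))


class TestSeparateSlopes:
    def test_same_noiseless_line_no_interaction(self):
        x = np.exp(np.linspace(0, 1, 40))
        y = np.exp(1.0 + 0.5 * np.log(x))
        groups = np.array(["a"] * 20 + ["b"] * 20)
        comp = separate_slopes_test(y, x, groups)
        assert comp.interaction_F == pytest.approx(0.0, abs=1e-8)
        assert comp.interaction_p == 1.0
        assert comp.fits["a"].slope == pytest.approx(comp.fits["b"].slope, abs=1e-10)

    def test_power_against_published_class_slopes(self):
        """Slopes 0.736 vs 0.367 at the study's group sizes, with noise
        matched to each class's r2, are detected at the rate the analytic
        power calculation predicts (~0.88 at alpha = 0.05).

        With noise calibrated to a class's r2, the slope's standard error is
        slope * sqrt((1 - r2)/r2) / sqrt(n) regardless of the predictor
        spread, so the detection rate is fully determined by the published
        slopes, r2 values and group sizes."""
        from scipy.stats import norm
        se_mod = 0.736 * np.sqrt((1 - 0.26) / 0.26) / np.sqrt(231)
        se_low = 0.367 * np.sqrt((1 - 0.08) / 0.08) / np.sqrt(212)
        se_diff = np.hypot(se_mod, se_low)
        power = norm.cdf((0.736 - 0.367) / se_diff - norm.ppf(0.975))
        hits = 0
        n_rep = 500
        for seed in range(n_rep):
            df = gen_classed_traits(212, 231, seed=seed)
            comp = separate_slopes_test(df["y"], df["Nmass"], df["p_class"])
            hits += comp.interaction_p < 0.05
        assert hits / n_rep > 0.8
        assert hits / n_rep == pytest.approx(power, abs=0.04)

    def test_null_calibration_type_I(self):
        """Under a common generating line the interaction test rejects at
        about the nominal 5% level."""
        rng = np.random.default_rng(11)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            lnx = rng.normal(3.0, 0.3, 120)
            y = np.exp(1.0 + 0.6 * lnx + rng.normal(0.0, 0.4, 120))
            groups = np.where(np.arange(120) % 2 == 0, "this", "rest")
            comp = separate_slopes_test(y, np.exp(lnx), groups)
            rejections += comp.interaction_p < 0.05
        assert rejections / n_rep == pytest.approx(0.05, abs=0.02)

    def test_small_group_excluded_with_warning_entry(self):
        x = np.exp(np.linspace(0, 1, 23))
        y = np.exp(0.5 * np.log(x) + 1.0)
        groups = np.array(["a"] * 10 + ["b"] * 11 + ["tiny"] * 2)
        comp = separate_slopes_test(y, x, groups)
        assert comp.excluded == ["tiny"]
        assert set(comp.groups) == {"a", "b"}


class TestInteractionModel:
    def test_exact_recovery_of_published_coefficients(self):
        # noiseless surface from the full-dataset Vcmax model
        rng = np.random.default_rng(5)
        lnN = rng.normal(3.0, 0.3, 60)
        lnP = rng.normal(0.0, 0.6, 60)
        y = np.exp(4.636 + 0.453 * lnN - 0.546 * lnP + 0.321 * lnN * lnP)
        r = np_interaction_model(y, np.exp(lnN), np.exp(lnP))
        assert r.intercept == pytest.approx(4.636, abs=1e-9)
        assert r.slope["lnN"] == pytest.approx(0.453, abs=1e-9)
        assert r.slope["lnP"] == pytest.approx(-0.546, abs=1e-9)
        assert r.slope["lnN:lnP"] == pytest.approx(0.321, abs=1e-9)
        assert r.r2 == pytest.approx(1.0, abs=1e-12)

    def test_constant_ma_column_rank_deficient(self):
        rng = np.random.default_rng(6)
        lnN = rng.normal(3.0, 0.3, 30)
        lnP = rng.normal(0.0, 0.6, 30)
        y = np.exp(1.0 + 0.5 * lnN + rng.normal(0, 0.1, 30))
        with pytest.raises(ValueError, match="collinear|rank"):
            np_interaction_model(y, np.exp(lnN), np.exp(lnP),
                                 Ma=np.full(30, 100.0))

    def test_term_tests_reported(self):
        rng = np.random.default_rng(8)
        lnN = rng.normal(3.0, 0.3, 200)
        lnP = rng.normal(0.0, 0.6, 200)
        y = np.exp(4.6 + 0.45 * lnN - 0.5 * lnP + 0.3 * lnN * lnP
                   + rng.normal(0, 0.3, 200))
        r = np_interaction_model(y, np.exp(lnN), np.exp(lnP))
        assert set(r.term_tests) == {"lnN", "lnP", "lnN:lnP"}
        F, p = r.term_tests["lnN:lnP"]
        assert F > 0 and 0 <= p <= 1


class TestThresholdSweep:
    def test_null_data_slopes_agree(self):
        rng = np.random.default_rng(9)
        lnN = rng.normal(3.0, 0.3, 400)
        y = np.exp(1.0 + 0.6 * lnN + rng.normal(0, 0.2, 400))
        P = np.exp(rng.normal(0.0, 0.6, 400))
        sweep = threshold_sweep(y, np.exp(lnN), P, [0.7, 0.92, 1.1])
        assert np.all(np.abs(sweep["slope_low"] - sweep["slope_moderate"]) < 0.2)
        assert np.all(sweep["interaction_p"] > 0.01)

    def test_classed_structure_orders_slopes(self):
        df = gen_classed_traits(300, 300, seed=4)
        sweep = threshold_sweep(df["y"], df["Nmass"], df["Pmass"],
                                [0.7, 0.92, 1.1])
        assert np.all(sweep["slope_moderate"] > sweep["slope_low"])

    def test_single_default_threshold_matches_separate_slopes(self):
        df = gen_classed_traits(100, 100, seed=2)
        sweep = threshold_sweep(df["y"], df["Nmass"], df["Pmass"], [0.92])
        labels = PClassing(0.92).labels(df["Pmass"].to_numpy())
        comp = separate_slopes_test(df["y"], df["Nmass"], labels)
        row = sweep.iloc[0]
        assert row["slope_low"] == comp.fits["low"].slope
        assert row["slope_moderate"] == comp.fits["moderate"].slope
        assert row["interaction_p"] == comp.interaction_p

    def test_small_class_flagged_not_dropped(self):
        df = gen_classed_traits(5, 200, seed=3)
        sweep = threshold_sweep(df["y"], df["Nmass"], df["Pmass"], [0.92])
        assert bool(sweep["flagged"].iloc[0])
        assert len(sweep) == 1

    def test_threshold_outside_range_rejected(self):
        df = gen_classed_traits(50, 50, seed=1)
        with pytest.raises(ValueError, match="outside"):
            threshold_sweep(df["y"], df["Nmass"], df["Pmass"], [99.0])


class TestDerivedContrasts:
    def test_fold_changes_from_published_slopes(self):
        assert fold_change(0.736, 5, ndigits=1) == 3.3
        assert fold_change(0.367, 5, ndigits=1) == 1.8
        assert fold_change(0.0, 17.0) == 1.0

    @given(slope=st.floats(-1.5, 1.5), x0=st.floats(0.1, 50.0),
           k=st.floats(0.2, 10.0))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_fold_change_matches_line_prediction(self, slope, x0, k):
        fit = _line_fit(slope, 0.7)
        assert fold_change(slope, k) == pytest.approx(
            fit.predict(k * x0) / fit.predict(x0), rel=1e-9)

    def test_class_contrast_published_vcmax_rows(self):
        low = _line_fit(0.367, 4.689)
        mod = _line_fit(0.736, 3.929)
        assert class_contrast_at(20.0, low, mod) == pytest.approx(41.3, abs=0.05)

    def test_class_contrast_published_jmax_rows(self):
        low = _line_fit(0.382, 5.366)
        mod = _line_fit(0.671, 4.825)
        assert class_contrast_at(20.0, low, mod) == pytest.approx(38.4, abs=0.05)

    def test_identical_fits_contrast_zero(self):
        f = _line_fit(0.5, 1.0)
        assert class_contrast_at(20.0, f, f) == pytest.approx(0.0, abs=1e-12)


def test_linear_ols_on_exact_line():
    x = np.linspace(10, 150, 30)
    r = linear_ols(17.5 + 1.52 * x, x)
    assert r.slope == pytest.approx(1.52, abs=1e-10)
    assert r.intercept == pytest.approx(17.5, abs=1e-8)
    assert r.transform == "none"


def test_pclassing_exhaustive_exclusive():
    labels = PClassing(0.92).labels(np.array([0.1, 0.91999, 0.92, 2.5]))
    assert list(labels) == ["low", "low", "moderate", "moderate"]
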