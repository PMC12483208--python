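"""Statistical layer: percent change, through-origin regression, mixed
models, CI prediction, power analysis, temporal outcomes."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from kneeload.stats import (
    BaselineError,
    RegressionResult,
    fit_origin_regression,
    fit_random_intercept_lmm,
    min_detectable_r2,
    normalize_outcome,
    percent_change,
    predict_with_ci,
    regression_power,
    temporal_outcomes,
)


def _table(rows):
    return pd.DataFrame(rows)


class TestPercentChange:
    def test_ten_percent_increase(self):
        tab = _table([
            {"subject_id": "a", "condition": "none", "early_peak": 3.0},
            {"subject_id": "a", "condition": "foot", "early_peak": 3.3},
        ])
        out = percent_change(tab, "early_peak")
        assert out["early_peak_pct"].tolist() == pytest.approx([0.0, 10.0])

    def test_two_baselines_averaged(self):
        tab = _table([
            {"subject_id": "a", "condition": "none", "early_peak": 2.9},
            {"subject_id": "a", "condition": "none", "early_peak": 3.1},
            {"subject_id": "a", "condition": "foot", "early_peak": 3.3},
        ])
        out = percent_change(tab, "early_peak")
        assert out["early_peak_pct"].iloc[2] == pytest.approx(10.0)

    def test_first_only_policy(self):
        tab = _table([
            {"subject_id": "a", "condition": "none", "early_peak": 3.0},
            {"subject_id": "a", "condition": "none", "early_peak": 4.0},
            {"subject_id": "a", "condition": "foot", "early_peak": 3.3},
        ])
        out = percent_change(tab, "early_peak", baseline_policy="first")
        assert out["early_peak_pct"].iloc[2] == pytest.approx(10.0)

    def test_missing_baseline_names_subject(self):
        tab = _table([
            {"subject_id": "s7", "condition": "foot", "early_peak": 3.3},
        ])
        with pytest.raises(BaselineError, match="s7"):
            percent_change(tab, "early_peak")


class TestOriginRegression:
    def _design(self):
        # the nine study conditions for one subject
        return np.array([
            [0, 0, 0], [2, 0, 0], [4, 0, 0], [0, 1.5, 0], [0, 3, 0],
            [0, 0, 1], [0, 0, 2], [2, 1.5, 1], [4, 3, 2]], dtype=float)

    def test_exact_coefficients_from_linear_truth(self):
        X = np.vstack([self._design()] * 3)
        beta = np.array([1.5, 2.1, 5.9])
        y = X @ beta
        fit = fit_origin_regression(y, X)
        assert fit.coefficients["m_thigh"] == pytest.approx(1.5, abs=1e-10)
        assert fit.coefficients["m_shank"] == pytest.approx(2.1, abs=1e-10)
        assert fit.coefficients["m_foot"] == pytest.approx(5.9, abs=1e-10)
        assert fit.pearson_r == pytest.approx(1.0, abs=1e-12)
        assert fit.df_resid == X.shape[0] - 3

    def test_single_predictor_exact(self):
        x = np.arange(1.0, 9.0)
        fit = fit_origin_regression(2 * x, x.reshape(-1, 1), names=["x"])
        assert fit.coefficients["x"] == pytest.approx(2.0, abs=1e-12)
        lo, hi = fit.conf_int["x"]
        assert hi - lo == pytest.approx(0.0, abs=1e-9)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = rng.integers(8, 40)
            X = rng.standard_normal((n, 3))
            y = X @ rng.uniform(-3, 3, 3) + rng.standard_normal(n)
            fit = fit_origin_regression(y, X)
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            got = np.array(list(fit.coefficients.values()))
            assert np.max(np.abs(got - beta)) < 1e-8

    def test_rank_deficiency_rejected(self):
        X = np.ones((10, 2))
        with pytest.raises(ValueError):
            fit_origin_regression(np.ones(10), X)


class TestMixedModel:
    def test_reduces_to_ols_without_subject_variance(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(0)
        X = rng.standard_normal((60, 3))
        y = X @ np.array([1.0, -2.0, 0.5]) + rng.standard_normal(60)
        ids = np.repeat(np.arange(6), 10)
        lmm = fit_random_intercept_lmm(y, X, ids)
        ols = sm.OLS(y, sm.add_constant(X)).fit()
        got = np.array(list(lmm.fixed_effects.values()))
        assert np.max(np.abs(got - ols.params)) < 0.05

    def test_variance_component_recovery(self):
        # balanced design, known variances (4, 1): median estimates over
        # seeds land near the truth
        sig_b2, sig2 = 4.0, 1.0
        est_b, est_e = [], []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            n_sub, n_rep = 10, 9
            X = rng.standard_normal((n_sub * n_rep, 2))
            b = rng.normal(0, np.sqrt(sig_b2), n_sub)
            ids = np.repeat(np.arange(n_sub), n_rep)
            y = X @ np.array([1.0, 2.0]) + b[ids] + rng.normal(
                0, np.sqrt(sig2), n_sub * n_rep)
            fit = fit_random_intercept_lmm(y, X, ids, names=["x1", "x2"])
            est_b.append(fit.random_intercept_var)
            est_e.append(fit.residual_var)
        assert np.median(est_b) == pytest.approx(sig_b2, rel=0.3)
        assert np.median(est_e) == pytest.approx(sig2, rel=0.15)

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            fit_random_intercept_lmm(np.zeros(10), np.zeros((10, 1)),
                                     np.zeros(10))


class TestPredictWithCi:
    def _fit(self):
        # a fit carrying the early-stance coefficients and their CIs
        return RegressionResult(
            coefficients={"m_thigh": 1.5, "m_shank": 2.1, "m_foot": 5.9},
            conf_int={"m_thigh": (0.8, 2.2), "m_shank": (1.2, 3.1),
                      "m_foot": (4.5, 7.3)},
            p_values={"m_thigh": 0.001, "m_shank": 0.001, "m_foot": 0.001},
            pearson_r=0.71, n_obs=90, df_resid=87)

    def test_zero_masses(self):
        assert predict_with_ci(self._fit(), [0, 0, 0]) == (0.0, 0.0, 0.0)

    def test_all_segment_high_point_prediction(self):
        point, lo, hi = predict_with_ci(self._fit(), [4.0, 3.0, 2.0])
        assert point == pytest.approx(24.1, abs=1e-9)
        assert lo < point < hi
        # coefficient-wise propagation of the CI endpoints
        assert lo == pytest.approx(0.8 * 4 + 1.2 * 3 + 4.5 * 2)
        assert hi == pytest.approx(2.2 * 4 + 3.1 * 3 + 7.3 * 2)

    def test_negative_masses_rejected(self):
        with pytest.raises(ValueError):
            predict_with_ci(self._fit(), [-1.0, 0.0, 0.0])


class TestMinDetectableR2:
    def test_study_power_analysis_value(self):
        r2 = min_detectable_r2(60, 3, 0.05, 0.8)
        assert round(r2, 2) == 0.17

    def test_monotone_decreasing_in_n(self):
        vals = [min_detectable_r2(n, 3) for n in (30, 60, 120, 240)]
        assert np.all(np.diff(vals) < 0)

    def test_monotone_increasing_in_power(self):
        assert (min_detectable_r2(60, 3, power=0.9)
                > min_detectable_r2(60, 3, power=0.8))

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            min_detectable_r2(3, 3)
        with pytest.raises(ValueError):
            min_detectable_r2(60, 3, alpha=1.5)

    def test_monte_carlo_rejection_rate(self):
        """Simulating at the returned R-squared reproduces the requested
        power (random multivariate-normal predictors)."""
        r2 = min_detectable_r2(60, 3, 0.05, 0.8)
        n, p, reps = 60, 3, 8000
        rng = np.random.default_rng(12345)
        c = np.sqrt(r2 / (1 - r2))
        fcrit = st.f.ppf(0.95, p, n - p - 1)
        rejections = 0
        X = rng.standard_normal((reps, n, p))
        eps = rng.standard_normal((reps, n))
        ones = np.ones((n, 1))
        for i in range(reps):
            y = c * X[i, :, 0] + eps[i]
            Z = np.hstack([ones, X[i]])
            beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
            resid = y - Z @ beta
            sse = resid @ resid
            sst = np.sum((y - y.mean()) ** 2)
            F = ((sst - sse) / p) / (sse / (n - p - 1))
            rejections += F > fcrit
        assert rejections / reps == pytest.approx(0.80, abs=0.015)

    def test_fixed_predictor_convention_available(self):
        r2_fixed = min_detectable_r2(60, 3, predictors="fixed")
        assert r2_fixed < min_detectable_r2(60, 3, predictors="random")
        # classical fixed-design value from the noncentral F directly
        ncp = 60 * r2_fixed / (1 - r2_fixed)
        power = st.ncf.sf(st.f.ppf(0.95, 3, 56), 3, 56, ncp)
        assert power == pytest.approx(0.8, abs=1e-4)


class TestTemporalOutcomes:
    def test_duty_factor_ratio(self, trial_none):
        row = temporal_outcomes(trial_none)
        assert row["duty_factor"] == pytest.approx(0.60, abs=0.02)
        assert row["stride_time"] == pytest.approx(trial_none.stride_time,
                                                   abs=0.005)

    def test_foot_loading_stride_time_effect(self, trial_none, trial_foot):
        base = temporal_outcomes(trial_none)
        loaded = temporal_outcomes(trial_foot)
        ratio = loaded["stride_time"] / base["stride_time"]
        assert ratio == pytest.approx(1.025, abs=0.002)

    def test_normalization_removes_proportional_effect(self):
        tab = pd.DataFrame({
            "moment": [10.0, 12.0, 14.0],
            "total_added_mass": [1.0, 1.2, 1.4],
        })
        out = normalize_outcome(tab, "moment", by=["total_added_mass"])
        assert np.allclose(out["moment_norm"], 10.0)


def test_regression_power_monotone_in_r2():
    lo = regression_power(0.05, 60, 3)
    hi = regression_power(0.3, 60, 3)
    assert 0 < lo < hi < 1
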