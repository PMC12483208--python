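"""Statistical layer: percent-change outcomes, through-origin regression,
random-intercept mixed models, coefficient-wise CI prediction, power
analysis, and temporal outcomes.

The headline analysis regresses percent change in early-/late-stance peak
contact force (relative to each subject's unweighted baseline) on the
added mass at thigh, shank and foot (% BW per leg) with no intercept:

    %change = a_thigh * m_thigh + a_shank * m_shank + a_foot * m_foot.

Results objects wrap statsmodels fits and expose coefficients, 95% CIs,
p-values and the Pearson correlation between observed and predicted
outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
from scipy.optimize import brentq

MASS_COLUMNS = ["m_thigh", "m_shank", "m_foot"]


class BaselineError(ValueError):
    pass


@dataclass
class RegressionResult:
    """Through-origin regression fit: %change per % BW added per leg."""

    coefficients: dict[str, float]
    conf_int: dict[str, tuple[float, float]]
    p_values: dict[str, float]
    pearson_r: float
    n_obs: int
    df_resid: int
    fitted: np.ndarray = field(repr=False, default=None)
    observed: np.ndarray = field(repr=False, default=None)

    def summary(self) -> str:
        lines = [
            f"Through-origin regression (n={self.n_obs}, df={self.df_resid}), "
            f"Pearson r (observed vs predicted) = {self.pearson_r:.3f}",
            f"{'predictor':<10}{'coef':>8}{'95% CI':>20}{'p':>12}",
        ]
        for name, b in self.coefficients.items():
            lo, hi = self.conf_int[name]
            lines.append(
                f"{name:<10}{b:>8.2f}{f'[{lo:.1f}, {hi:.1f}]':>20}"
                f"{self.p_values[name]:>12.3g}"
            )
        return "\n".join(lines)


@dataclass
class MixedModelResult:
    """Random-intercept (subject) linear mixed model fit."""

    fixed_effects: dict[str, float]
    p_values: dict[str, float]
    conf_int: dict[str, tuple[float, float]]
    random_intercept_var: float
    residual_var: float
    loglike: float
    n_obs: int
    converged: bool

    def summary(self) -> str:
        lines = [
            f"Random-intercept LMM (n={self.n_obs}), "
            f"sigma_b^2={self.random_intercept_var:.4g}, "
            f"sigma^2={self.residual_var:.4g}, llf={self.loglike:.2f}",
        ]
        for name, b in self.fixed_effects.items():
            lines.append(f"  {name}: {b:.3f} (p={self.p_values[name]:.3g})")
        return "\n".join(lines)


def percent_change(
    outcomes: pd.DataFrame,
    value_col: str,
    baseline_condition: str = "none",
    baseline_policy: str = "mean",
) -> pd.DataFrame:
    """Percent change of an outcome from each subject's no-mass baseline.

    The protocol runs two unweighted trials (initial/final); the baseline
    is their mean by default (``baseline_policy='first'`` uses the first
    only).  Baseline rows are retained with value 0.
    """
    out = outcomes.copy()
    pct = np.empty(len(out))
    for subject, grp in out.groupby("subject_id"):
        base_rows = grp[grp["condition"] == baseline_condition]
        if base_rows.empty:
            raise BaselineError(
                f"subject {subject}: no baseline ({baseline_condition!r}) "
                f"rows for outcome {value_col!r}"
            )
        if baseline_policy == "first":
            base = float(base_rows[value_col].iloc[0])
        else:
            base = float(base_rows[value_col].mean())
        pct[grp.index] = 100.0 * (grp[value_col] - base) / base
    out[f"{value_col}_pct"] = pct
    return out


def fit_origin_regression(y, X, names: list[str] | None = None) -> RegressionResult:
    """Least squares through the origin with t-based CIs and p-values.

    ``X`` is (n, p) predictors (typically the three segment masses); no
    intercept is added, matching the y = a*x model; degrees of freedom are
    n - p.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.size:
        X = X.T
    n, p = X.shape
    if n < p + 1:
        raise ValueError(f"need at least {p + 1} observations, got {n}")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("rank-deficient predictor matrix")
    names = names or (MASS_COLUMNS[:p] if p <= 3 else [f"x{i}" for i in range(p)])
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int(alpha=0.05)
    observed = y
    fitted = fit.fittedvalues
    if np.std(fitted) > 0 and np.std(observed) > 0:
        r = float(st.pearsonr(observed, fitted)[0])
    else:
        r = np.nan
    return RegressionResult(
        coefficients={nm: float(b) for nm, b in zip(names, fit.params)},
        conf_int={nm: (float(lo), float(hi)) for nm, (lo, hi) in zip(names, np.asarray(ci))},
        p_values={nm: float(pv) for nm, pv in zip(names, fit.pvalues)},
        pearson_r=r,
        n_obs=n,
        df_resid=int(fit.df_resid),
        fitted=np.asarray(fitted),
        observed=observed,
    )


def fit_random_intercept_lmm(y, X, subject_ids,
                             names: list[str] | None = None) -> MixedModelResult:
    """Random-intercept model y = Xb + b_subject + eps, REML.

    Fixed effects get Wald p-values; the model is fit with an intercept-only
    random effect per subject.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.size:
        X = X.T
    subject_ids = np.asarray(subject_ids)
    if len(np.unique(subject_ids)) < 2:
        raise ValueError("need at least two subjects for a random intercept")
    n, p = X.shape
    names = names or (MASS_COLUMNS[:p] if p <= 3 else [f"x{i}" for i in range(p)])
    all_names = ["intercept"] + names
    exog = sm.add_constant(X)
    import warnings

    # degenerate (noise-free) data make the REML profile singular; fall
    # back to OLS, to which the mixed model reduces when the between-
    # subject variance is zero
    ols = sm.OLS(y, exog).fit()
    if float(ols.scale) < 1e-12 * max(1.0, float(np.var(y))):
        fit = None
    else:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.MixedLM(y, exog, groups=subject_ids).fit(
                    reml=True, method="lbfgs")
        except np.linalg.LinAlgError:
            fit = None
    if fit is None:
        ci = np.asarray(ols.conf_int())
        return MixedModelResult(
            fixed_effects={nm: float(b) for nm, b in zip(all_names, ols.params)},
            p_values={nm: float(pv) for nm, pv in zip(all_names, ols.pvalues)},
            conf_int={nm: (float(lo), float(hi))
                      for nm, (lo, hi) in zip(all_names, ci)},
            random_intercept_var=0.0,
            residual_var=float(ols.scale),
            loglike=float(ols.llf),
            n_obs=n,
            converged=True,
        )
    params = fit.fe_params
    pvals = fit.pvalues[: len(all_names)]
    ci = np.asarray(fit.conf_int())[: len(all_names)]
    return MixedModelResult(
        fixed_effects={nm: float(b) for nm, b in zip(all_names, params)},
        p_values={nm: float(pv) for nm, pv in zip(all_names, pvals)},
        conf_int={nm: (float(lo), float(hi)) for nm, (lo, hi) in zip(all_names, ci)},
        random_intercept_var=float(np.asarray(fit.cov_re)[0, 0]),
        residual_var=float(fit.scale),
        loglike=float(fit.llf),
        n_obs=n,
        converged=bool(fit.converged),
    )


def predict_with_ci(fit: RegressionResult, masses: dict[str, float] | np.ndarray
                    ) -> tuple[float, float, float]:
    """Point prediction with coefficient-wise CI propagation.

    Bounds sum each coefficient's 95% CI endpoint times its (nonnegative)
    mass — the interval construction used for the all-segment
    interaction-effect check, not a proper prediction interval.
    """
    if isinstance(masses, dict):
        m = np.array([masses.get(k, masses.get(k.replace("m_", ""), 0.0))
                      for k in fit.coefficients])
    else:
        m = np.asarray(masses, dtype=float)
    if np.any(m < 0):
        raise ValueError("masses must be nonnegative")
    point = float(sum(b * mi for b, mi in zip(fit.coefficients.values(), m)))
    lower = float(sum(fit.conf_int[nm][0] * mi
                      for nm, mi in zip(fit.coefficients, m)))
    upper = float(sum(fit.conf_int[nm][1] * mi
                      for nm, mi in zip(fit.coefficients, m)))
    return point, lower, upper


def regression_power(r2: float, n: int, p: int, alpha: float = 0.05,
                     predictors: str = "random", n_quad: int = 400) -> float:
    """Power of the overall F-test of a p-predictor linear model.

    ``predictors='fixed'`` uses the classical fixed-design noncentral F
    with ncp = n*R2/(1-R2).  ``predictors='random'`` (default) averages the
    conditional power over the design distribution for multivariate-normal
    predictors (conditional ncp f2*K with K ~ chi-square(n-1)), the
    unconditional power appropriate when the predictor values are
    themselves sampled.
    """
    dfd = n - p - 1
    fcrit = st.f.ppf(1 - alpha, p, dfd)
    f2 = r2 / (1.0 - r2)
    if predictors == "fixed":
        return float(st.ncf.sf(fcrit, p, dfd, n * f2))
    u = (np.arange(n_quad) + 0.5) / n_quad
    k = st.chi2.ppf(u, n - 1)
    return float(np.mean(st.ncf.sf(fcrit, p, dfd, f2 * k)))


def min_detectable_r2(n: int, p: int, alpha: float = 0.05, power: float = 0.8,
                      predictors: str = "random") -> float:
    """Smallest R-squared detectable by the overall F-test.

    Solved by bisection to 1e-6 on the monotone power curve.
    """
    if n <= p + 1:
        raise ValueError("need n > p + 1")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    lo, hi = 1e-9, 1.0 - 1e-9
    if regression_power(hi, n, p, alpha, predictors) < power:
        raise ValueError("requested power unattainable at this sample size")
    return float(brentq(
        lambda r2: regression_power(r2, n, p, alpha, predictors) - power,
        lo, hi, xtol=1e-6,
    ))


def temporal_outcomes(trial, segmentation=None) -> dict:
    """Temporal/kinematic/kinetic outcome row for one trial.

    Stride time and duty factor from force-plate segmentation; peak knee
    flexion angle in early stance, peak extension (minimum) angle in late
    stance; optional normalizations are applied downstream.
    """
    from .emg import detect_stance

    if segmentation is None:
        segmentation = detect_stance(trial.grf["fy"], trial.fs_grf)
    if segmentation.n_stances < 2 or segmentation.stride_time is None:
        raise ValueError("need at least two heel strikes for stride time")
    hs, to = trial.stance_events[trial.analyzed_stance]
    t = trial.time_angles
    mask = (t >= hs) & (t <= to)
    knee = trial.q["knee_r"][mask]
    pct = np.linspace(0, 100, mask.sum())
    early = pct <= 50
    late = pct > 50
    m = trial.condition.masses()
    return {
        "subject_id": trial.subject.subject_id,
        "condition": trial.condition.name,
        "m_thigh": m["thigh"], "m_shank": m["shank"], "m_foot": m["foot"],
        "stride_time": float(segmentation.stride_time),
        "duty_factor": float(segmentation.duty_factor),
        "peak_knee_flexion_early": float(np.max(knee[early])),
        "peak_knee_extension_late": float(np.min(knee[late])),
        "total_added_mass": trial.condition.total_pct / 100.0 * trial.subject.mass * 2,
    }


def normalize_outcome(table: pd.DataFrame, value_col: str,
                      by: list[str]) -> pd.DataFrame:
    """Divide an outcome by covariates (e.g. stride time, total worn mass).

    Removes a purely proportional covariate effect exactly; rows where a
    covariate is zero keep the raw value.
    """
    out = table.copy()
    scaled = out[value_col].astype(float).copy()
    for cov in by:
        denom = out[cov].astype(float)
        scaled = np.where(denom > 0, scaled / denom, scaled)
    out[f"{value_col}_norm"] = scaled
    return out
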