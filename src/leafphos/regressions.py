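"""Trait regression engine: log-log OLS, SMA, separate-slopes tests,
N x P interaction models, threshold sweeps and derived contrasts.

All bivariate trait relationships are fitted on natural-log-transformed
data (traits are approximately log-normal), reported with denominator
degrees of freedom.  Standardised major axis (SMA) fits are the symmetric
secondary approach: slope = sign(r) * sd(ln y) / sd(ln x), line through the
means; the identity |b_SMA| = |b_OLS| / |r| holds on every dataset.

Leaf-P classing uses a P_mass threshold (default 0.92 mg g-1): leaves with
P_mass below it are "low P", at or above it "moderate P".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

__all__ = [
    "RegressionResult",
    "SlopeComparison",
    "PClassing",
    "log_ols",
    "linear_ols",
    "sma_fit",
    "separate_slopes_test",
    "np_interaction_model",
    "threshold_sweep",
    "fold_change",
    "class_contrast_at",
]


@dataclass
class RegressionResult:
    """One fitted line (or multi-term model) with its test statistics."""

    slope: float | dict[str, float]
    intercept: float
    r2: float
    F: float
    p: float
    df_den: int
    n: int
    method: str = "OLS"          # OLS | SMA
    transform: str = "ln"        # ln | none
    term_tests: dict[str, tuple[float, float]] = field(default_factory=dict)

    def predict(self, x: np.ndarray | float) -> np.ndarray | float:
        """Evaluate the fitted single-predictor line on the response scale."""
        if isinstance(self.slope, dict):
            raise ValueError("predict() supports single-predictor fits only")
        if self.transform == "ln":
            return np.exp(self.intercept + self.slope * np.log(x))
        return self.intercept + self.slope * np.asarray(x, dtype=float)


@dataclass
class SlopeComparison:
    """Per-group lines plus the interaction (separate-slopes) F-test."""

    groups: list
    fits: dict
    interaction_p: float
    interaction_F: float
    common_slope: RegressionResult
    excluded: list = field(default_factory=list)


@dataclass(frozen=True)
class PClassing:
    """Exhaustive, exclusive low/moderate leaf-P classing."""

    threshold: float = 0.92

    def __post_init__(self):
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")

    def labels(self, pmass: np.ndarray) -> np.ndarray:
        pmass = np.asarray(pmass, dtype=float)
        return np.where(pmass < self.threshold, "low", "moderate")


def _check_positive(name: str, v: np.ndarray) -> None:
    bad = np.flatnonzero(~(np.asarray(v, dtype=float) > 0))
    if bad.size:
        raise ValueError(f"{name} must be strictly positive for log transform; "
                         f"offending rows: {bad[:10].tolist()}")


def _ols_result(y: np.ndarray, x: np.ndarray, transform: str) -> RegressionResult:
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    # Guard the degenerate constant-y case (F undefined, r2 -> 0).
    with np.errstate(divide="ignore", invalid="ignore"):
        f = float(fit.fvalue) if np.isfinite(fit.fvalue) else 0.0
        p = float(fit.f_pvalue) if np.isfinite(fit.f_pvalue) else 1.0
        r2 = float(fit.rsquared) if np.isfinite(fit.rsquared) else 0.0
    return RegressionResult(
        slope=float(fit.params[1]), intercept=float(fit.params[0]),
        r2=r2, F=f, p=p, df_den=int(fit.df_resid), n=len(y),
        method="OLS", transform=transform,
    )


def log_ols(y, x) -> RegressionResult:
    """OLS of ln(y) on ln(x)."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if len(y) != len(x):
        raise ValueError("y and x must have equal length")
    if len(y) < 3:
        raise ValueError("need at least 3 observations")
    _check_positive("y", y)
    _check_positive("x", x)
    return _ols_result(np.log(y), np.log(x), "ln")


def linear_ols(y, x) -> RegressionResult:
    """OLS of y on x without transformation (e.g. Jmax vs Vcmax lines)."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 observations")
    return _ols_result(y, x, "none")


def sma_fit(y, x) -> RegressionResult:
    """Standardised major axis fit of ln(y) on ln(x).

    Symmetric in y and x up to inversion of the slope; significance is the
    test of r = 0, as conventional for SMA.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 observations")
    _check_positive("y", y)
    _check_positive("x", x)
    ly, lx = np.log(y), np.log(x)
    sy, sx = ly.std(ddof=1), lx.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("zero variance in x or y on the log scale")
    r, p = st.pearsonr(ly, lx)
    slope = float(np.sign(r) if r != 0 else 1.0) * sy / sx
    intercept = float(ly.mean() - slope * lx.mean())
    n = len(y)
    F = r * r / (1 - r * r) * (n - 2) if abs(r) < 1 else np.inf
    return RegressionResult(
        slope=float(slope), intercept=intercept, r2=float(r * r), F=float(F),
        p=float(p), df_den=n - 2, n=n, method="SMA", transform="ln",
    )


def separate_slopes_test(y, x, groups, transform: str = "ln") -> SlopeComparison:
    """Test for separate rather than parallel slopes across groups.

    Fits the full interaction model ln y ~ ln x * group against the reduced
    parallel-slopes model ln y ~ ln x + group; the F-test of the interaction
    block gives ``interaction_p``.  Groups with fewer than 3 points are
    excluded with a warning entry.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    groups = np.asarray(groups)
    if transform == "ln":
        _check_positive("y", y)
        _check_positive("x", x)
        ly, lx = np.log(y), np.log(x)
    else:
        ly, lx = y, x

    labels, excluded = [], []
    for g in pd.unique(groups):
        if np.sum(groups == g) >= 3:
            labels.append(g)
        else:
            excluded.append(g)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups with n >= 3")
    keep = np.isin(groups, labels)
    ly, lx, groups = ly[keep], lx[keep], groups[keep]
    n, k = len(ly), len(labels)

    # Full model: per-group intercepts and slopes.
    dummies = np.column_stack([(groups == g).astype(float) for g in labels])
    X_full = np.column_stack([dummies, dummies * lx[:, None]])
    X_red = np.column_stack([dummies, lx])
    ssr_full = sm.OLS(ly, X_full).fit().ssr
    red_fit = sm.OLS(ly, X_red).fit()
    ssr_red = red_fit.ssr
    df_int = k - 1
    df_res = n - 2 * k
    tss = float(np.sum((ly - ly.mean()) ** 2))
    eps = 1e-12 * max(tss, 1.0)
    if ssr_full <= eps:  # numerically noiseless full model
        if ssr_red - ssr_full > eps:  # reduced model genuinely worse
            F_int, p_int = np.inf, 0.0
        else:  # no evidence against parallel lines
            F_int, p_int = 0.0, 1.0
    else:
        F_int = max(((ssr_red - ssr_full) / df_int) / (ssr_full / df_res), 0.0)
        p_int = float(st.f.sf(F_int, df_int, df_res))

    fitter = log_ols if transform == "ln" else linear_ols
    fits = {g: fitter(y[keep][groups == g], x[keep][groups == g]) for g in labels}
    common = RegressionResult(
        slope=float(red_fit.params[-1]),
        intercept=float(red_fit.params[0]),
        r2=float(red_fit.rsquared), F=float(red_fit.fvalue)
        if np.isfinite(red_fit.fvalue) else 0.0,
        p=float(red_fit.f_pvalue) if np.isfinite(red_fit.f_pvalue) else 1.0,
        df_den=int(red_fit.df_resid), n=n, method="OLS", transform=transform,
    )
    return SlopeComparison(
        groups=list(labels), fits=fits, interaction_p=float(p_int),
        interaction_F=float(F_int), common_slope=common, excluded=excluded,
    )


def np_interaction_model(y, N, P, Ma=None) -> RegressionResult:
    """Multiple regression ln y ~ ln N + ln P + ln N * ln P (+ ln Ma).

    Returns all coefficients in ``slope`` (dict), whole-model F/p/r2 and
    term-wise F-tests (1-df, F = t^2) in ``term_tests``.
    """
    y = np.asarray(y, dtype=float)
    N = np.asarray(N, dtype=float)
    P = np.asarray(P, dtype=float)
    for nm, v in (("y", y), ("N", N), ("P", P)):
        _check_positive(nm, v)
    cols = {"lnN": np.log(N), "lnP": np.log(P),
            "lnN:lnP": np.log(N) * np.log(P)}
    if Ma is not None:
        Ma = np.asarray(Ma, dtype=float)
        _check_positive("Ma", Ma)
        cols["lnMa"] = np.log(Ma)
    X = np.column_stack([np.ones_like(y)] + list(cols.values()))
    if len(y) < X.shape[1] + 3:
        raise ValueError("too few observations for the model")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            f"rank-deficient design; collinear terms among {list(cols)}")
    fit = sm.OLS(np.log(y), X).fit()
    names = list(cols)
    slopes = {nm: float(b) for nm, b in zip(names, fit.params[1:])}
    term_tests = {
        nm: (float(t) ** 2, float(p))
        for nm, t, p in zip(names, fit.tvalues[1:], fit.pvalues[1:])
    }
    return RegressionResult(
        slope=slopes, intercept=float(fit.params[0]), r2=float(fit.rsquared),
        F=float(fit.fvalue), p=float(fit.f_pvalue), df_den=int(fit.df_resid),
        n=len(y), method="OLS", transform="ln", term_tests=term_tests,
    )


def threshold_sweep(y, x, P, thresholds, min_class_n: int = 10) -> pd.DataFrame:
    """Low/moderate class slopes and interaction p across P thresholds.

    Each row reports both class slopes, group sizes and the separate-slopes
    interaction p at one threshold; thresholds leaving a class with fewer
    than ``min_class_n`` members are flagged, never dropped.
    """
    P = np.asarray(P, dtype=float)
    lo, hi = P.min(), P.max()
    rows = []
    for thr in thresholds:
        if not (lo < thr < hi):
            raise ValueError(f"threshold {thr} outside observed P range ({lo}, {hi})")
        labels = PClassing(thr).labels(P)
        comp = separate_slopes_test(y, x, labels)
        n_low = int(np.sum(labels == "low"))
        n_mod = int(np.sum(labels == "moderate"))
        rows.append({
            "threshold": thr,
            "slope_low": comp.fits["low"].slope,
            "slope_moderate": comp.fits["moderate"].slope,
            "n_low": n_low, "n_moderate": n_mod,
            "interaction_p": comp.interaction_p,
            "flagged": min(n_low, n_mod) < min_class_n,
        })
    return pd.DataFrame(rows)


def fold_change(slope: float, factor: float, ndigits: int | None = None) -> float:
    """Multiplicative change in y for a `factor`-fold change in x on a
    log-log line: factor ** slope."""
    if factor <= 0:
        raise ValueError("factor must be > 0")
    fc = factor ** slope
    return round(fc, ndigits) if ndigits is not None else fc


def class_contrast_at(x0: float, fit_low: RegressionResult,
                      fit_mod: RegressionResult) -> float:
    """Percent increase of the moderate-P over the low-P fitted line at x0.

    Both fits must be on the ln scale; returns
    100 * (exp[(a_m + b_m ln x0) - (a_l + b_l ln x0)] - 1).
    """
    for f in (fit_low, fit_mod):
        if f.transform != "ln":
            raise ValueError("class_contrast_at requires ln-scale fits")
    lx = np.log(x0)
    diff = (fit_mod.intercept + fit_mod.slope * lx) - (
        fit_low.intercept + fit_low.slope * lx)
    return 100.0 * (np.exp(diff) - 1.0)
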