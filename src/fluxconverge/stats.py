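"""Statistical kernel for method-comparison analyses.

Contains:

* major-axis (model II) regression with a Jolicoeur-type F-based confidence
  interval for the slope and a seeded-bootstrap fallback;
* normality-gated paired comparison (paired t vs Wilcoxon signed-rank,
  gated on a Shapiro-Wilk test of the pair differences);
* Welch two-sample comparison with an exact-permutation fallback for
  degenerate groups;
* inverse-uncertainty-weighted least-squares covariate screens with
  Breusch-Pagan heteroskedasticity gating and White (HC0) robust inference;
* type-II two-way ANOVA;
* leave-one-out outlier sensitivity for the screens.

Major-axis regression is used for method comparison because both variables
carry errors of similar magnitude: it fits the first principal axis of the
(x, y) scatter rather than conditioning on x.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.formula.api import ols as _ols_formula
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.diagnostic import het_breuschpagan

__all__ = [
    "RegressionResult", "PairedTestResult", "GroupCompareResult",
    "AnovaResult", "UndefinedAxisError", "SingularDesignError",
    "ma_regression", "paired_compare", "group_compare", "weighted_screen",
    "two_way_anova", "outlier_sensitivity", "significance_marker",
]

DEFAULT_ALPHA_GATE = 0.05
_BOOTSTRAP_RESAMPLES = 2000
_BOOTSTRAP_SEED = 20161214


class UndefinedAxisError(ValueError):
    """The principal axis of the scatter is undefined (circular scatter)."""


class SingularDesignError(ValueError):
    """The regression design matrix is rank-deficient (e.g. constant predictor)."""


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    slope_ci95: tuple[float, float]
    r_squared: float
    p_value: float
    n: int
    heteroskedastic: bool = False
    inference_method: str = "standard"  # standard | white_robust | pearson_r2 | bootstrap
    shapiro_p: Optional[float] = None   # residual-normality check, informational

    def to_dict(self) -> dict:
        d = vars(self).copy()
        d["slope_ci95"] = list(self.slope_ci95)
        return d


@dataclass
class PairedTestResult:
    mean_difference: float
    sem: float
    test_used: str           # paired_t | wilcoxon_signed_rank | degenerate
    shapiro_p: float
    p_value: float
    n: int

    def to_dict(self) -> dict:
        return vars(self).copy()


@dataclass
class GroupCompareResult:
    mean_a: float
    sem_a: float
    n_a: int
    mean_b: float
    sem_b: float
    n_b: int
    p_value: float
    test_used: str  # welch_t | permutation


@dataclass
class AnovaResult:
    p_a: float
    p_b: float
    p_interaction: float     # NaN when not estimable
    interaction_estimable: bool
    degenerate: bool = False


def significance_marker(p: float) -> str:
    """Tier markers: ** for P<0.01, * for P<0.05, + for P<0.10."""
    if not np.isfinite(p):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.10:
        return "+"
    return ""


def _sem(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / math.sqrt(len(x))) if len(x) > 1 else float("nan")


# ---------------------------------------------------------------------------
# Major-axis regression

def _ma_slope(sxx: float, syy: float, sxy: float) -> float:
    if sxy == 0.0:
        if math.isclose(sxx, syy, rel_tol=1e-12, abs_tol=1e-300):
            raise UndefinedAxisError("scatter has no preferred axis (Sxy=0, Sxx=Syy)")
        if syy > sxx:
            raise UndefinedAxisError("major axis is vertical (Sxy=0, Syy>Sxx)")
        return 0.0
    return (syy - sxx + math.hypot(syy - sxx, 2.0 * sxy)) / (2.0 * sxy)


def _bootstrap_slope_ci(x: np.ndarray, y: np.ndarray, alpha: float) -> tuple[float, float]:
    rng = np.random.default_rng(_BOOTSTRAP_SEED)
    n = len(x)
    slopes = []
    for _ in range(_BOOTSTRAP_RESAMPLES):
        idx = rng.integers(0, n, size=n)
        xb, yb = x[idx], y[idx]
        sxx, syy = np.var(xb, ddof=1), np.var(yb, ddof=1)
        sxy = np.cov(xb, yb, ddof=1)[0, 1]
        try:
            slopes.append(_ma_slope(sxx, syy, sxy))
        except UndefinedAxisError:
            continue
    if len(slopes) < _BOOTSTRAP_RESAMPLES // 2:
        return (float("nan"), float("nan"))
    lo, hi = np.percentile(slopes, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return (float(lo), float(hi))


def ma_regression(
    x: Sequence[float], y: Sequence[float], alpha: float = 0.05
) -> RegressionResult:
    """Major-axis regression of y on x.

    The slope is the first principal axis of the sample covariance matrix,

        b = (Syy - Sxx + sqrt((Syy - Sxx)^2 + 4 Sxy^2)) / (2 Sxy),

    the intercept passes the axis through the centroid, and R^2 is the
    squared Pearson correlation.  The slope confidence interval is the
    classical F-based interval on the axis angle (Jolicoeur): with
    eigenvalues l1 >= l2 of the covariance matrix,

        sin(2 phi) = 2 sqrt(F l1 l2 / (n - 2)) / (l1 - l2),

    and the slope limits are tan(theta -+ phi).  When that interval is
    undefined or brackets the vertical, a percentile bootstrap interval
    (2000 resamples, fixed seed) is reported and flagged.  The p-value is
    the Pearson correlation test (slope "significance" in model II
    regression is the hypothesis of no association).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y):
        raise ValueError("x and y must have equal length")
    if n < 3:
        raise ValueError("major-axis regression needs n >= 3")
    sxx = float(np.var(x, ddof=1))
    syy = float(np.var(y, ddof=1))
    if sxx + syy == 0.0:
        raise UndefinedAxisError("all points identical")
    sxy = float(np.cov(x, y, ddof=1)[0, 1])
    slope = _ma_slope(sxx, syy, sxy)
    intercept = float(np.mean(y) - slope * np.mean(x))

    if sxx > 0 and syy > 0:
        r = float(np.corrcoef(x, y)[0, 1])
        r2 = r * r
        p_value = float(sps.pearsonr(x, y).pvalue) if abs(r) < 1 else 0.0
    else:
        r2, p_value = 0.0, 1.0

    # Jolicoeur F-based confidence interval on the axis angle
    disc = math.hypot(syy - sxx, 2.0 * sxy)
    l1 = (sxx + syy + disc) / 2.0
    l2 = (sxx + syy - disc) / 2.0
    inference = "standard"
    if l1 <= l2 or l2 < 0:
        ci = (slope, slope)  # exact line: zero-width interval
        if l2 > 0:
            inference = "bootstrap"
            ci = _bootstrap_slope_ci(x, y, alpha)
    else:
        fcrit = float(sps.f.ppf(1 - alpha, 1, n - 2))
        arg = 2.0 * math.sqrt(max(fcrit * l1 * l2 / (n - 2), 0.0)) / (l1 - l2)
        theta = math.atan(slope)
        if arg >= 1.0:
            inference = "bootstrap"
            ci = _bootstrap_slope_ci(x, y, alpha)
        else:
            phi = 0.5 * math.asin(arg)
            lo_ang, hi_ang = theta - phi, theta + phi
            if hi_ang >= math.pi / 2 or lo_ang <= -math.pi / 2:
                # interval brackets the vertical: fall back to bootstrap
                inference = "bootstrap"
                ci = _bootstrap_slope_ci(x, y, alpha)
            else:
                ci = (math.tan(lo_ang), math.tan(hi_ang))
    lo, hi = min(ci), max(ci)
    return RegressionResult(
        slope=slope, intercept=intercept, slope_ci95=(lo, hi),
        r_squared=r2, p_value=p_value, n=n, inference_method=inference,
    )


# ---------------------------------------------------------------------------
# Paired and two-sample comparisons

def paired_compare(
    a: Sequence[float],
    b: Sequence[float],
    alpha_gate: float = DEFAULT_ALPHA_GATE,
) -> PairedTestResult:
    """Compare paired samples via a normality-gated test on d = a - b.

    Shapiro-Wilk is applied to the pair differences; when its p-value is at
    or above `alpha_gate` the differences are treated as normal and a
    two-sided paired t-test is used, otherwise a two-sided Wilcoxon
    signed-rank test (exact null distribution for n <= 25 without ties,
    normal approximation with continuity correction above; zero differences
    dropped; tied ranks averaged).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b):
        raise ValueError("paired samples must have equal length")
    n = len(a)
    if n < 3:
        raise ValueError("paired comparison needs n >= 3")
    d = a - b
    if np.all(d == 0):
        return PairedTestResult(0.0, 0.0, "degenerate", 1.0, 1.0, n)
    if np.all(d == d[0]):
        # constant nonzero differences: t-test is exact (sd = 0 -> p = 0 limit)
        return PairedTestResult(float(d[0]), 0.0, "degenerate", 1.0, 0.0, n)
    shapiro_p = float(sps.shapiro(d).pvalue)
    if shapiro_p >= alpha_gate:
        stat = sps.ttest_rel(a, b)
        return PairedTestResult(
            float(d.mean()), _sem(d), "paired_t", shapiro_p, float(stat.pvalue), n
        )
    nonzero = d[d != 0]
    if len(nonzero) == 0:
        return PairedTestResult(0.0, _sem(d), "degenerate", shapiro_p, 1.0, n)
    mode = "exact" if len(nonzero) <= 25 else "approx"
    try:
        res = sps.wilcoxon(nonzero, zero_method="wilcox", correction=True, method=mode)
    except ValueError:
        res = sps.wilcoxon(nonzero, zero_method="wilcox", correction=True, method="approx")
    return PairedTestResult(
        float(d.mean()), _sem(d), "wilcoxon_signed_rank", shapiro_p, float(res.pvalue), n
    )


def group_compare(
    values_a: Sequence[float], values_b: Sequence[float]
) -> GroupCompareResult:
    """Welch two-sample t-test; exact permutation fallback for degenerate groups."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if np.array_equal(np.sort(a), np.sort(b)):
        p, test = 1.0, "welch_t"
    elif np.var(a) == 0 or np.var(b) == 0:
        res = sps.permutation_test(
            (a, b),
            lambda u, v, axis=-1: np.mean(u, axis=axis) - np.mean(v, axis=axis),
            permutation_type="independent",
            alternative="two-sided",
            n_resamples=np.inf if len(a) + len(b) <= 12 else 9999,
            random_state=_BOOTSTRAP_SEED,
        )
        p, test = float(res.pvalue), "permutation"
    else:
        res = sps.ttest_ind(a, b, equal_var=False)
        p, test = float(res.pvalue), "welch_t"
    return GroupCompareResult(
        mean_a=float(a.mean()), sem_a=_sem(a), n_a=len(a),
        mean_b=float(b.mean()), sem_b=_sem(b), n_b=len(b),
        p_value=p, test_used=test,
    )


# ---------------------------------------------------------------------------
# Weighted covariate screens

def _design_matrix(predictor) -> tuple[np.ndarray, bool]:
    """Numeric column, or dummy-coded factor (drop-first). Returns (X, is_factor)."""
    s = pd.Series(predictor)
    numeric = pd.api.types.is_numeric_dtype(s) and not isinstance(
        s.dtype, pd.CategoricalDtype
    )
    if numeric:
        X = s.to_numpy(dtype=float).reshape(-1, 1)
        if np.ptp(X) == 0:
            raise SingularDesignError("constant predictor")
        return X, False
    cats = s.astype(str)
    dummies = pd.get_dummies(cats, drop_first=True)
    if dummies.shape[1] == 0:
        raise SingularDesignError("constant predictor (single category)")
    return dummies.to_numpy(dtype=float), True


def weighted_screen(
    response: Sequence[float],
    predictor,
    weights: Sequence[float],
    alpha_gate: float = DEFAULT_ALPHA_GATE,
    weight_power: float = 1.0,
) -> RegressionResult:
    """Weighted least-squares screen of a response against one covariate.

    Weights are the inverse flux uncertainty 1/s (weight_power=1); set
    weight_power=2 for classical inverse-variance 1/s^2 weighting.
    Categorical predictors are dummy-coded and tested with an overall F-test.
    Homoskedasticity of the weighted residuals is tested with Breusch-Pagan
    at `alpha_gate`; under heteroskedasticity, inference switches to White
    HC0 robust covariance and R^2 is reported as the squared Pearson
    correlation between response and fitted values.
    """
    y = np.asarray(response, dtype=float)
    w = np.asarray(weights, dtype=float) ** weight_power
    if np.any(w <= 0):
        raise ValueError("weights must be > 0")
    X, is_factor = _design_matrix(predictor)
    k = X.shape[1]
    n = len(y)
    if n < k + 2:
        raise ValueError(f"need n >= {k + 2} observations for {k} predictor column(s)")
    exog = sm.add_constant(X)
    model = sm.WLS(y, exog, weights=w)
    res = model.fit()

    shapiro_p = float(sps.shapiro(res.wresid).pvalue) if n >= 3 else float("nan")
    # auxiliary regression of squared weighted residuals on the covariates
    bp_p = float(het_breuschpagan(res.wresid, exog)[1])
    hetero = bp_p < alpha_gate

    if hetero:
        res_inf = res.get_robustcov_results(cov_type="HC0")
        inference = "white_robust"
        fitted = np.asarray(res.fittedvalues)
        r = np.corrcoef(y, fitted)[0, 1] if np.std(fitted) > 0 else 0.0
        r2 = float(r * r)
    else:
        res_inf = res
        inference = "standard"
        r2 = float(res.rsquared)

    if k == 1:
        p_value = float(np.atleast_1d(res_inf.pvalues)[1])
    else:
        contrast = np.hstack([np.zeros((k, 1)), np.eye(k)])
        p_value = float(res_inf.f_test(contrast).pvalue)

    slope = float(res.params[1]) if k == 1 else float("nan")
    lo = hi = float("nan")
    if k == 1:
        ci = np.atleast_2d(res_inf.conf_int())
        lo, hi = float(ci[1, 0]), float(ci[1, 1])
    return RegressionResult(
        slope=slope, intercept=float(res.params[0]), slope_ci95=(lo, hi),
        r_squared=min(max(r2, 0.0), 1.0), p_value=p_value, n=n,
        heteroskedastic=hetero,
        inference_method=inference,
        shapiro_p=shapiro_p,
    )


def two_way_anova(response, factor_a, factor_b) -> AnovaResult:
    """Type-II two-way ANOVA (unbalanced-safe) with interaction.

    When some factor-level crossing is empty the interaction is inestimable:
    main effects are then tested in the additive model and the interaction
    p-value is NaN.  A constant response is reported as degenerate with all
    p-values NaN.
    """
    df = pd.DataFrame({
        "y": np.asarray(response, dtype=float),
        "a": pd.Series(factor_a).astype(str).to_numpy(),
        "b": pd.Series(factor_b).astype(str).to_numpy(),
    })
    cross = pd.crosstab(df["a"], df["b"])
    if (cross.to_numpy() > 0).sum() < 3:
        raise ValueError("two-way ANOVA needs at least 3 occupied cells")
    if np.ptp(df["y"].to_numpy()) == 0:
        return AnovaResult(float("nan"), float("nan"), float("nan"), False, degenerate=True)
    estimable = not (cross.to_numpy() == 0).any()
    if estimable:
        fit = _ols_formula("y ~ C(a) * C(b)", data=df).fit()
        tab = anova_lm(fit, typ=2)
        p_int = float(tab.loc["C(a):C(b)", "PR(>F)"])
        if not np.isfinite(p_int):
            estimable = False
    if not estimable:
        p_int = float("nan")
    fit_add = _ols_formula("y ~ C(a) + C(b)", data=df).fit()
    tab_add = anova_lm(fit_add, typ=2)
    if estimable:
        p_a = float(tab.loc["C(a)", "PR(>F)"])
        p_b = float(tab.loc["C(b)", "PR(>F)"])
    else:
        p_a = float(tab_add.loc["C(a)", "PR(>F)"])
        p_b = float(tab_add.loc["C(b)", "PR(>F)"])
    return AnovaResult(p_a, p_b, p_int, estimable)


def outlier_sensitivity(
    response: Sequence[float],
    predictor,
    weights: Sequence[float],
    alpha_gate: float = DEFAULT_ALPHA_GATE,
    thresholds: tuple[float, ...] = (0.05, 0.10),
) -> pd.DataFrame:
    """Leave-one-out sensitivity of a weighted screen's p-value.

    Refits the screen once per omitted observation and flags points whose
    omission moves the p-value across any of the significance thresholds
    (in either direction).  Returns a DataFrame with one row per point:
    ``p_without`` and ``influential``.
    """
    y = np.asarray(response, dtype=float)
    w = np.asarray(weights, dtype=float)
    pred = pd.Series(predictor).reset_index(drop=True)
    n = len(y)
    if n < 5:
        raise ValueError("outlier sensitivity needs n >= 5")
    p_full = weighted_screen(y, pred, w, alpha_gate).p_value
    rows = []
    for i in range(n):
        mask = np.arange(n) != i
        try:
            p_i = weighted_screen(y[mask], pred[mask], w[mask], alpha_gate).p_value
        except (SingularDesignError, ValueError):
            p_i = float("nan")
        crossed = any(
            np.isfinite(p_i) and ((p_full < t) != (p_i < t)) for t in thresholds
        )
        rows.append({"index": i, "p_without": p_i, "influential": crossed})
    out = pd.DataFrame(rows).set_index("index")
    out.attrs["p_full"] = p_full
    return out
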