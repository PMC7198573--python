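"""Per-gene stimulated-vs-baseline regression.

For each gene the stimulated abundance is regressed on the baseline abundance
across individuals, first by ordinary least squares — a straight line
``cpm_stim ~ cpm_base`` and a quadratic ``cpm_stim ~ cpm_base + cpm_base²`` —
and, when the OLS residuals of both fits violate normality (Shapiro–Wilk)
and/or homoscedasticity (Breusch–Pagan against the fitted values), by a
non-parametric Kendall–Theil line instead.

Three hypothesis tests drive the downstream categorisation: slope vs 0,
slope vs 1 and intercept vs 0 (t tests under OLS; Kendall-tau association and
a sign test under Kendall–Theil), plus a t test on the quadratic coefficient
for OLS fits.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.diagnostic import het_breuschpagan

from .preprocess import GeneResponseProfile, StimcatError, ValidationError

logger = logging.getLogger("stimcat")

#: Residual-diagnostic significance level for the OLS→Kendall–Theil fallback.
DIAGNOSTIC_ALPHA = 0.05

#: Relative residual-variance floor below which a fit counts as degenerate
#: (zero-residual); p-values then follow the exact-null convention.
_DEGENERATE_RTOL = 1e-12


class FitError(StimcatError):
    """A regression could not be fitted."""


@dataclass
class FitResult:
    """Regression output for one gene."""

    gene_id: str
    method: str  # "ols" | "kendall_theil"
    slope: float
    intercept: float
    p_slope_zero: float
    p_slope_one: float
    p_intercept_zero: float
    n: int
    quad_coef: float | None = None
    r_squared: float | None = None
    p_quad: float | None = None
    resid_normality_p: float | None = None
    resid_homoscedasticity_p: float | None = None
    degenerate: bool = False


def _check_profile(profile: GeneResponseProfile, min_n: int = 3) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(profile.cpm_base, dtype=float)
    y = np.asarray(profile.cpm_stim, dtype=float)
    if profile.n < min_n:
        raise FitError(f"{profile.gene_id}: need at least {min_n} individuals, got {profile.n}")
    if np.ptp(x) == 0:
        raise FitError(f"{profile.gene_id}: baseline abundance is constant; slope undefined")
    return x, y


def _t_pvalue(estimate: float, null: float, se: float, df: int, ss_resid: float, ss_total: float) -> float:
    """Two-sided t-test p-value with the zero-residual convention.

    When the fit is exact (no residual variance) the standard error collapses;
    a test whose null holds exactly reports p=1, any other reports p=0.
    """
    if ss_resid <= _DEGENERATE_RTOL * max(ss_total, 1.0) or se == 0 or df <= 0:
        return 1.0 if np.isclose(estimate, null, rtol=1e-9, atol=1e-12) else 0.0
    t = (estimate - null) / se
    return float(2 * stats.t.sf(abs(t), df))


def _is_degenerate(ss_resid: float, ss_total: float) -> bool:
    return ss_resid <= _DEGENERATE_RTOL * max(ss_total, 1.0)


def fit_linear_ols(profile: GeneResponseProfile) -> FitResult:
    """OLS fit of ``cpm_stim ~ cpm_base`` with slope-vs-0/1 and intercept tests."""
    x, y = _check_profile(profile, min_n=3)
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    intercept, slope = res.params
    se_int, se_slope = res.bse
    df = int(res.df_resid)
    ss_resid = float(res.ssr)
    ss_total = float(res.centered_tss)
    degenerate = _is_degenerate(ss_resid, ss_total)
    r2 = 1.0 if degenerate else float(res.rsquared)
    return FitResult(
        gene_id=profile.gene_id,
        method="ols",
        slope=float(slope),
        intercept=float(intercept),
        p_slope_zero=_t_pvalue(slope, 0.0, se_slope, df, ss_resid, ss_total),
        p_slope_one=_t_pvalue(slope, 1.0, se_slope, df, ss_resid, ss_total),
        p_intercept_zero=_t_pvalue(intercept, 0.0, se_int, df, ss_resid, ss_total),
        r_squared=r2,
        n=profile.n,
        degenerate=degenerate,
    )


def fit_quadratic_ols(profile: GeneResponseProfile) -> FitResult:
    """OLS fit of ``cpm_stim ~ cpm_base + cpm_base²``; tests the quadratic term."""
    x, y = _check_profile(profile, min_n=4)
    if len(np.unique(x)) < 3:
        raise FitError(f"{profile.gene_id}: need ≥3 distinct baseline values for a quadratic fit")
    X = np.column_stack([np.ones_like(x), x, x * x])
    if np.linalg.matrix_rank(X) < 3:
        raise FitError(f"{profile.gene_id}: rank-deficient quadratic design")
    res = sm.OLS(y, X).fit()
    intercept, slope, quad = res.params
    df = int(res.df_resid)
    ss_resid = float(res.ssr)
    ss_total = float(res.centered_tss)
    degenerate = _is_degenerate(ss_resid, ss_total)
    r2 = 1.0 if degenerate else float(res.rsquared)
    return FitResult(
        gene_id=profile.gene_id,
        method="ols",
        slope=float(slope),
        intercept=float(intercept),
        quad_coef=float(quad),
        p_slope_zero=_t_pvalue(slope, 0.0, res.bse[1], df, ss_resid, ss_total),
        p_slope_one=_t_pvalue(slope, 1.0, res.bse[1], df, ss_resid, ss_total),
        p_intercept_zero=_t_pvalue(intercept, 0.0, res.bse[0], df, ss_resid, ss_total),
        p_quad=_t_pvalue(quad, 0.0, res.bse[2], df, ss_resid, ss_total),
        r_squared=r2,
        n=profile.n,
        degenerate=degenerate,
    )


def check_residual_assumptions(
    fit: FitResult, profile: GeneResponseProfile, alpha: float = DIAGNOSTIC_ALPHA
) -> tuple[float, float, bool]:
    """Shapiro–Wilk normality and Breusch–Pagan homoscedasticity of OLS residuals.

    Breusch–Pagan regresses the squared residuals on the fitted values. The
    two tests are Bonferroni-combined so that a clean fit is falsely declared
    deviant at rate ``alpha`` overall, not per test: ``ok = both p ≥ alpha/2``.
    A degenerate (zero-residual or residual-df-free) fit cannot be tested and
    is accepted with a warning. Returns ``(normality_p, homoscedasticity_p, ok)``.
    """
    if fit.method != "ols":
        raise ValidationError("residual diagnostics apply to OLS fits only")
    x = np.asarray(profile.cpm_base, dtype=float)
    y = np.asarray(profile.cpm_stim, dtype=float)
    if fit.quad_coef is not None:
        fitted = fit.intercept + fit.slope * x + fit.quad_coef * x * x
        n_params = 3
    else:
        fitted = fit.intercept + fit.slope * x
        n_params = 2
    resid = y - fitted
    ss_total = float(np.sum((y - y.mean()) ** 2))
    if fit.n - n_params <= 1 or _is_degenerate(float(resid @ resid), ss_total):
        logger.warning("%s: degenerate fit, residual diagnostics skipped", fit.gene_id)
        return float("nan"), float("nan"), True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # shapiro warns for n>5000; harmless here
        norm_p = float(stats.shapiro(resid).pvalue)
    exog = sm.add_constant(fitted)
    try:
        het_p = float(het_breuschpagan(resid, exog)[1])
    except (ValueError, np.linalg.LinAlgError):
        het_p = float("nan")
    level = alpha / 2
    ok = bool(norm_p >= level and (np.isnan(het_p) or het_p >= level))
    return norm_p, het_p, ok


def theil_sen(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Theil–Sen line: median pairwise slope, intercept = median(y − slope·x).

    Pairs with tied x are skipped.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0:
        raise FitError("all baseline values tied; Theil–Sen slope undefined")
    slope, intercept, _, _ = stats.theilslopes(y, x, method="joint")
    return float(slope), float(intercept)


def _kendall_p(x: np.ndarray, v: np.ndarray) -> float:
    """Two-sided tau-b association p; no association evidence (constant v) → 1."""
    if np.ptp(v) == 0:
        return 1.0
    res = stats.kendalltau(x, v)
    p = float(res.pvalue)
    return 1.0 if np.isnan(p) else p


def fit_kendall_theil(profile: GeneResponseProfile) -> FitResult:
    """Non-parametric Kendall–Theil fit with tau-based slope tests.

    slope vs 0 is the Kendall-tau association test of x and y; slope vs 1 the
    same test applied to x and (y − x) — the shift that maps the slope-one null
    onto the slope-zero machinery; intercept vs 0 is a sign test of the paired
    offsets y − x. The offsets, not the fitted residuals y − slope·x, carry
    the intercept information in the only regime where the categorisation
    consults this test (slope indistinguishable from one); a sign test of the
    fitted residuals would instead be dominated by slope-estimation error,
    since the abundances are strictly positive and far from x = 0.
    """
    x, y = _check_profile(profile, min_n=3)
    slope, intercept = theil_sen(x, y)
    offsets = y - x
    nonzero = offsets[offsets != 0]
    if len(nonzero) == 0:
        p_int = 1.0
    else:
        k = int(np.sum(nonzero > 0))
        p_int = float(stats.binomtest(k, len(nonzero), 0.5, alternative="two-sided").pvalue)
    return FitResult(
        gene_id=profile.gene_id,
        method="kendall_theil",
        slope=slope,
        intercept=intercept,
        p_slope_zero=_kendall_p(x, y),
        p_slope_one=_kendall_p(x, y - x),
        p_intercept_zero=p_int,
        n=profile.n,
    )


def fit_gene(
    profile: GeneResponseProfile,
    diagnostic_alpha: float = DIAGNOSTIC_ALPHA,
    fallback_policy: str = "both",
) -> FitResult:
    """Fit one gene: OLS linear + quadratic with diagnostics, Kendall–Theil fallback.

    ``fallback_policy`` controls when the non-parametric fit replaces OLS:
    ``"both"`` (default) falls back only when the residuals of *both* OLS fits
    violate the assumptions; ``"either"`` falls back when either fit does. When
    OLS is kept, the returned coefficients and slope/intercept tests come from
    the linear fit, with the quadratic coefficient and its test attached.
    """
    if fallback_policy not in ("both", "either"):
        raise ValidationError(f"unknown fallback_policy {fallback_policy!r}")
    lin = fit_linear_ols(profile)
    try:
        quad = fit_quadratic_ols(profile)
    except FitError:
        quad = None

    lin_norm, lin_het, lin_ok = check_residual_assumptions(lin, profile, diagnostic_alpha)
    if quad is not None:
        quad_norm, quad_het, quad_ok = check_residual_assumptions(quad, profile, diagnostic_alpha)
    else:
        quad_ok = lin_ok

    if fallback_policy == "both":
        use_kt = not lin_ok and not quad_ok
    else:
        use_kt = not lin_ok or not quad_ok

    if use_kt:
        kt = fit_kendall_theil(profile)
        kt.resid_normality_p = lin_norm
        kt.resid_homoscedasticity_p = lin_het
        return kt

    lin.resid_normality_p = lin_norm
    lin.resid_homoscedasticity_p = lin_het
    if quad is not None:
        lin.quad_coef = quad.quad_coef
        lin.p_quad = quad.p_quad
    return lin
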