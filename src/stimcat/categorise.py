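"""Multiple-testing correction and response-category assignment.

Raw per-gene p-values are Benjamini–Hochberg adjusted within each test family
(slope vs 0, slope vs 1, intercept vs 0, quadratic term, paired mean response,
CV equality) across the informative gene set, and each gene is then assigned
one or more response categories:

* ``no_response`` — slope indistinguishable from 1 and intercept from 0;
* ``uncorrelated`` — slope indistinguishable from 0: individuals respond, but
  independently of their baseline;
* ``constant`` — slope ≈ 1 with a significant intercept: a uniform additive
  response across individuals;
* ``baseline_dependent_linear`` — slope significantly different from both 0
  and 1 (greater than one, less than one, or negative);
* ``baseline_dependent_quadratic`` — significant curvature, saturating
  (concave) or exponential (convex).

Categories are multi-label; a single ``primary`` label is also reported using
the precedence quadratic > linear > uncorrelated > constant > no_response
(most specific evidence first).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import GeneResponseProfile, ValidationError
from .regression import FitResult

CATEGORIES = (
    "no_response",
    "uncorrelated",
    "constant",
    "baseline_dependent_linear",
    "baseline_dependent_quadratic",
)

#: Primary-label precedence, most specific evidence first.
PRECEDENCE = (
    "baseline_dependent_quadratic",
    "baseline_dependent_linear",
    "uncorrelated",
    "constant",
    "no_response",
)

#: The three main reporting rows; both baseline-dependent flavours share one.
MAIN_CATEGORIES = ("uncorrelated", "constant", "baseline_dependent")


@dataclass
class CategoryAssignment:
    gene_id: str
    flags: set[str]
    primary: str
    slope_side: str | None = None  # gt1 | lt1 | negative, for linear genes
    quad_shape: str | None = None  # saturating | exponential, for quadratic genes
    mean_response_p: float | None = None
    adjusted: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = self.flags - set(CATEGORIES)
        if bad:
            raise ValidationError(f"unknown category flags: {sorted(bad)}")
        if self.primary not in self.flags:
            raise ValidationError("primary label must be one of the flags")


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    Sort ascending, multiply p_(i) by m/i, enforce monotonicity by a running
    minimum from the largest rank, cap at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValidationError("bh_adjust expects a 1-d vector")
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def bh_adjust_masked(pvalues) -> np.ndarray:
    """BH adjustment over the non-NaN entries; NaNs pass through.

    Used for families (e.g. the quadratic term) that only exist for a subset
    of genes: the family size m is the number of genes actually tested.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        out[mask] = bh_adjust(p[mask])
    return out


def assign_category(fit: FitResult, adjusted: dict[str, float], alpha: float = 0.05) -> CategoryAssignment:
    """Assign response-category flags from BH-adjusted p-values for one gene.

    ``adjusted`` must carry ``p_slope_zero``, ``p_slope_one`` and
    ``p_intercept_zero``; ``p_quad`` is consulted when present (OLS fits).
    """
    for key in ("p_slope_zero", "p_slope_one", "p_intercept_zero"):
        if key not in adjusted or adjusted[key] is None or np.isnan(adjusted[key]):
            raise ValidationError(f"{fit.gene_id}: missing adjusted p-value {key!r}")
    if not 0 < alpha < 1:
        raise ValidationError("alpha must lie in (0, 1)")

    sig_zero = adjusted["p_slope_zero"] <= alpha
    sig_one = adjusted["p_slope_one"] <= alpha
    sig_int = adjusted["p_intercept_zero"] <= alpha
    p_quad = adjusted.get("p_quad")
    sig_quad = p_quad is not None and not np.isnan(p_quad) and p_quad <= alpha

    flags: set[str] = set()
    if not sig_zero:
        flags.add("uncorrelated")
    if sig_zero and sig_one:
        flags.add("baseline_dependent_linear")
    if sig_quad:
        flags.add("baseline_dependent_quadratic")
    if sig_zero and not sig_one and sig_int:
        flags.add("constant")
    if not sig_one and not sig_int and not sig_quad:
        flags.add("no_response")
    if not flags:  # unreachable for the tree above, guarded for safety
        flags.add("no_response")

    slope_side = None
    if "baseline_dependent_linear" in flags:
        if fit.slope < 0:
            slope_side = "negative"
        elif fit.slope > 1:
            slope_side = "gt1"
        else:
            slope_side = "lt1"
    quad_shape = None
    if "baseline_dependent_quadratic" in flags:
        if fit.quad_coef is None:
            raise ValidationError(f"{fit.gene_id}: quadratic flag without a quadratic coefficient")
        quad_shape = "saturating" if fit.quad_coef < 0 else "exponential"

    primary = next(c for c in PRECEDENCE if c in flags)
    return CategoryAssignment(
        gene_id=fit.gene_id,
        flags=flags,
        primary=primary,
        slope_side=slope_side,
        quad_shape=quad_shape,
        adjusted=dict(adjusted),
    )


def paired_mean_test(profile: GeneResponseProfile) -> tuple[float, str]:
    """Wilcoxon signed-rank test of stimulated vs baseline abundance.

    Returns the one-sided p-value for the favoured direction together with a
    direction hint (``up`` when stimulated abundance tends to exceed baseline,
    ``down`` for the reverse, ``none`` for no paired differences). The caller
    BH-adjusts the p-values across the gene set and keeps the hint only when
    the adjusted p clears alpha.
    """
    if profile.n < 3:
        raise ValidationError(f"{profile.gene_id}: paired test needs at least 3 individuals")
    diff = profile.cpm_stim - profile.cpm_base
    if np.all(diff == 0):
        return 1.0, "none"
    p_up = float(stats.wilcoxon(diff, alternative="greater").pvalue)
    p_down = float(stats.wilcoxon(diff, alternative="less").pvalue)
    if p_up <= p_down:
        return p_up, "up"
    return p_down, "down"


def _main_category_flags(flags: set[str]) -> set[str]:
    out = set()
    if "uncorrelated" in flags:
        out.add("uncorrelated")
    if "constant" in flags:
        out.add("constant")
    if flags & {"baseline_dependent_linear", "baseline_dependent_quadratic"}:
        out.add("baseline_dependent")
    return out


def summarise_categories(
    assignments: list[CategoryAssignment], cv_results: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Counts per main response category, total and by variability direction.

    A gene carrying several flags contributes once to each flagged main
    category. ``cv_results`` (gene_id, direction) supplies the convergent and
    divergent columns; without it they are zero.
    """
    direction = {}
    if cv_results is not None and len(cv_results):
        direction = dict(zip(cv_results["gene_id"], cv_results["direction"]))
    rows = []
    for cat in MAIN_CATEGORIES:
        total = conv = div = 0
        for a in assignments:
            if cat in _main_category_flags(a.flags):
                total += 1
                d = direction.get(a.gene_id, "none")
                conv += d == "convergent"
                div += d == "divergent"
        rows.append({"category": cat, "total": total, "convergent": conv, "divergent": div})
    return pd.DataFrame(rows)


def assignments_frame(assignments: list[CategoryAssignment]) -> pd.DataFrame:
    """Flatten assignments to a table (flags semicolon-joined, adjusted p columns)."""
    rows = []
    for a in assignments:
        row = {
            "gene_id": a.gene_id,
            "flags": ";".join(sorted(a.flags)),
            "primary": a.primary,
            "slope_side": a.slope_side or "",
            "quad_shape": a.quad_shape or "",
            "mean_response_p": a.mean_response_p,
        }
        for key, val in a.adjusted.items():
            row[f"adj_{key}"] = val
        rows.append(row)
    return pd.DataFrame(rows)
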