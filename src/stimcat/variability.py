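"""Individual variability in response: CV comparison and age-stratified bootstrap.

A marker whose coefficient of variation differs significantly between baseline
and stimulated abundances shows high individual variability in response:
``convergent`` when variability collapses on stimulation (CV_base > CV_stim),
``divergent`` when it expands (CV_stim > CV_base). Equality of CVs is tested
with the Feltz–Miller asymptotic test (chi-squared, k−1 df), and adjusted for
multiple testing across genes with Benjamini–Hochberg.

The age-stratified comparison classifies the immature individuals directly and
compares against the mature individuals resampled with replacement at the
immature sample size (1000 draws by default), reporting bootstrap mean counts
per direction with empirical 95% intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import SampleTable, ValidationError
from .categorise import bh_adjust

DIRECTIONS = ("convergent", "divergent", "none")


@dataclass
class CvTestResult:
    gene_id: str
    cv_base: float
    cv_stim: float
    statistic: float
    p: float
    p_adj: float = float("nan")
    direction: str = "none"


@dataclass
class AgeStratifiedSummary:
    """Counts of significant markers per direction for one age class.

    For the directly analysed class the mean equals the observed count and the
    interval collapses onto it; for the bootstrapped class the mean and the
    empirical 2.5/97.5 percentiles summarise the resampling distribution.
    """

    age_class: str
    n_boot: int
    counts: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]

    def __post_init__(self) -> None:
        for d in self.counts:
            if not self.ci_low[d] <= self.counts[d] <= self.ci_high[d]:
                raise ValidationError(f"{self.age_class}/{d}: interval must contain the mean")


def coefficient_of_variation(values) -> float:
    """Sample standard deviation (n−1 denominator) divided by the mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValidationError("CV requires at least 2 values")
    mean = v.mean()
    if mean <= 0:
        raise ValidationError("CV requires a positive mean")
    return float(v.std(ddof=1) / mean)


def _cv_rows(mat: np.ndarray) -> np.ndarray:
    """Row-wise CV of a genes × individuals matrix (n−1 denominator)."""
    mean = mat.mean(axis=-1)
    if np.any(mean <= 0):
        raise ValidationError("CV requires positive means for every gene")
    return mat.std(axis=-1, ddof=1) / mean


def feltz_miller_matrix(
    base: np.ndarray, stim: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised Feltz–Miller asymptotic CV-equality test, row-wise.

    ``base`` and ``stim`` are ``(..., n_base)`` / ``(..., n_stim)`` arrays;
    each leading entry is one gene (or one bootstrap draw of one gene).
    Returns ``(cv_base, cv_stim, statistic, p)``. Under CV equality the
    statistic is asymptotically chi-squared with 1 df.
    """
    base = np.asarray(base, dtype=float)
    stim = np.asarray(stim, dtype=float)
    if base.shape[-1] < 2 or stim.shape[-1] < 2:
        raise ValidationError("CV-equality test requires at least 2 values per group")
    cv_b = _cv_rows(base)
    cv_s = _cv_rows(stim)
    m_b = base.shape[-1] - 1
    m_s = stim.shape[-1] - 1
    pooled = (m_b * cv_b + m_s * cv_s) / (m_b + m_s)
    denom = pooled**2 * (0.5 + pooled**2)
    stat = np.zeros_like(pooled)
    nz = denom > 0
    stat[nz] = (m_b * (cv_b - pooled) ** 2 + m_s * (cv_s - pooled) ** 2)[nz] / denom[nz]
    p = np.where(denom > 0, stats.chi2.sf(stat, df=1), 1.0)
    # both groups constant: no variability to compare
    p = np.where((cv_b == 0) & (cv_s == 0), 1.0, p)
    return cv_b, cv_s, stat, p


def cv_equality_test(base, stim) -> tuple[float, float]:
    """Feltz–Miller test for equality of two CVs; returns (statistic, p)."""
    base = np.atleast_2d(np.asarray(base, dtype=float))
    stim = np.atleast_2d(np.asarray(stim, dtype=float))
    _, _, stat, p = feltz_miller_matrix(base, stim)
    return float(stat[0]), float(p[0])


def cv_test_genes(base: pd.DataFrame, stim: pd.DataFrame) -> pd.DataFrame:
    """Per-gene CV-equality tests on aligned genes × individuals cpm matrices."""
    if not base.index.equals(stim.index):
        raise ValidationError("base and stim matrices must share gene order")
    cv_b, cv_s, stat, p = feltz_miller_matrix(base.to_numpy(), stim.to_numpy())
    return pd.DataFrame(
        {
            "gene_id": base.index,
            "cv_base": cv_b,
            "cv_stim": cv_s,
            "statistic": stat,
            "p": p,
        }
    ).reset_index(drop=True)


def classify_variability(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """BH-adjust CV-test p-values and attach convergent/divergent directions."""
    out = results.copy()
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    sig = out["p_adj"] <= alpha
    out["direction"] = "none"
    out.loc[sig & (out["cv_base"] > out["cv_stim"]), "direction"] = "convergent"
    out.loc[sig & (out["cv_stim"] > out["cv_base"]), "direction"] = "divergent"
    return out


def cross_tabulate(assignments, cv_results: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Convergent/divergent counts per main category, plus orphan divergents.

    Orphans are divergent markers whose only response flag is ``no_response``:
    markers that on average do not respond yet whose individual variability
    expands on stimulation.
    """
    from .categorise import MAIN_CATEGORIES, _main_category_flags

    by_gene = {a.gene_id: a for a in assignments}
    missing = set(cv_results["gene_id"]) - set(by_gene)
    if missing:
        raise ValidationError(f"cv results for genes without assignments: {sorted(missing)[:5]}")
    direction = dict(zip(cv_results["gene_id"], cv_results["direction"]))
    rows = []
    for cat in MAIN_CATEGORIES:
        conv = div = 0
        for a in assignments:
            if cat in _main_category_flags(a.flags):
                d = direction.get(a.gene_id, "none")
                conv += d == "convergent"
                div += d == "divergent"
        rows.append({"category": cat, "convergent": conv, "divergent": div})
    orphans = [
        g
        for g, d in direction.items()
        if d == "divergent" and by_gene[g].flags == {"no_response"}
    ]
    return pd.DataFrame(rows), sorted(orphans)


def _count_directions(base: np.ndarray, stim: np.ndarray, alpha: float) -> dict[str, int]:
    """Classify one draw (genes × individuals arrays) and count directions."""
    cv_b, cv_s, _, p = feltz_miller_matrix(base, stim)
    p_adj = bh_adjust(p)
    sig = p_adj <= alpha
    return {
        "convergent": int(np.sum(sig & (cv_b > cv_s))),
        "divergent": int(np.sum(sig & (cv_s > cv_b))),
    }


def age_stratified_resample(
    base: pd.DataFrame,
    stim: pd.DataFrame,
    age_class: pd.Series,
    alpha: float = 0.05,
    n_boot: int = 1000,
    seed: int | np.random.SeedSequence = 0,
    draw_size: int | None = None,
) -> tuple[AgeStratifiedSummary, AgeStratifiedSummary]:
    """Compare variability classification between immature and mature individuals.

    ``base``/``stim`` are genes × individuals cpm matrices with identical
    column (individual) order; ``age_class`` maps individual id to
    ``immature``/``mature``. The immature subset is classified once; the
    mature subset is resampled with replacement ``n_boot`` times at
    ``draw_size`` (default: the immature sample size) and classified per draw.
    """
    if n_boot < 1:
        raise ValidationError("n_boot must be at least 1")
    if not base.columns.equals(stim.columns) or not base.index.equals(stim.index):
        raise ValidationError("base and stim matrices must be aligned")
    age = age_class.reindex(base.columns)
    groups = {
        cls: [ind for ind in base.columns if age.get(ind) == cls]
        for cls in ("immature", "mature")
    }
    for cls, members in groups.items():
        if len(members) < 3:
            raise ValidationError(f"age class {cls!r} has {len(members)} individuals; need ≥3")

    imm = groups["immature"]
    imm_counts = _count_directions(
        base[imm].to_numpy(), stim[imm].to_numpy(), alpha
    )
    imm_summary = AgeStratifiedSummary(
        age_class="immature",
        n_boot=1,
        counts={d: float(imm_counts[d]) for d in imm_counts},
        ci_low={d: float(imm_counts[d]) for d in imm_counts},
        ci_high={d: float(imm_counts[d]) for d in imm_counts},
    )

    mat = groups["mature"]
    size = len(imm) if draw_size is None else draw_size
    if size < 2:
        raise ValidationError("bootstrap draw size must be at least 2")
    rng = np.random.default_rng(seed)
    mat_base = base[mat].to_numpy()
    mat_stim = stim[mat].to_numpy()
    draws = {d: np.empty(n_boot) for d in ("convergent", "divergent")}
    for b in range(n_boot):
        idx = rng.integers(0, len(mat), size=size)
        counts = _count_directions(mat_base[:, idx], mat_stim[:, idx], alpha)
        for d in draws:
            draws[d][b] = counts[d]
    means = {d: float(draws[d].mean()) for d in draws}
    mat_summary = AgeStratifiedSummary(
        age_class="mature",
        n_boot=n_boot,
        counts=means,
        # clamp so the interval always contains the mean: with very sparse
        # counts both empirical percentiles can sit at zero while rare
        # nonzero draws pull the mean just above them
        ci_low={d: min(float(np.percentile(draws[d], 2.5)), means[d]) for d in draws},
        ci_high={d: max(float(np.percentile(draws[d], 97.5)), means[d]) for d in draws},
    )
    return imm_summary, mat_summary


def age_summary_frame(summaries, seed: int | None = None) -> pd.DataFrame:
    rows = []
    for s in summaries:
        for d, mean in s.counts.items():
            rows.append(
                {
                    "age_class": s.age_class,
                    "direction": d,
                    "mean_count": mean,
                    "ci_low": s.ci_low[d],
                    "ci_high": s.ci_high[d],
                    "n_boot": s.n_boot,
                    "seed": seed if seed is not None else "",
                }
            )
    return pd.DataFrame(rows)
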