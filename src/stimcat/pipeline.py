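"""End-to-end orchestration: configuration, the full analysis run, and reporting.

``run_pipeline`` chains the stages — unexpressed-gene filter, cpm
normalisation, informative filter, per-gene regression with the
Kendall–Theil fallback, per-family BH adjustment, category assignment, the
paired mean-response check for uncorrelated markers, CV-based
convergent/divergent classification, and (when age classes are present) the
age-stratified bootstrap — and collects every stage table plus a run log.
All randomness flows from one root seed; stages derive child seeds by name.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__
from .preprocess import (
    CountMatrix,
    SampleTable,
    CpmMatrix,
    StimcatError,
    ValidationError,
    compute_cpm,
    filter_informative,
    filter_unexpressed,
    mean_variance_profile,
    pair_profiles,
    paired_matrices,
    UNEXPRESSED_CPM,
    INFORMATIVE_CPM,
)
from .regression import FitResult, fit_gene
from .categorise import (
    CategoryAssignment,
    assign_category,
    assignments_frame,
    bh_adjust,
    bh_adjust_masked,
    paired_mean_test,
    summarise_categories,
    CATEGORIES,
)
from .variability import (
    age_stratified_resample,
    age_summary_frame,
    classify_variability,
    cross_tabulate,
    cv_test_genes,
)
from .simulate import seed_sequence

logger = logging.getLogger("stimcat")

#: BH test families adjusted separately across the informative gene set.
TEST_FAMILIES = ("p_slope_zero", "p_slope_one", "p_intercept_zero", "p_quad")


@dataclass
class RunConfig:
    """Thresholds and policies for one analysis run."""

    unexpressed_cpm: float = UNEXPRESSED_CPM
    informative_cpm: float = INFORMATIVE_CPM
    alpha: float = 0.05
    diagnostic_alpha: float = 0.05
    fallback_policy: str = "both"  # "both" | "either"
    bh_policy: str = "per_family"  # "per_family" | "global"
    n_boot: int = 1000
    boot_draw_size: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.unexpressed_cpm <= 0 or self.informative_cpm <= 0:
            raise ValidationError("cpm thresholds must be positive")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")
        if self.bh_policy not in ("per_family", "global"):
            raise ValidationError(f"unknown bh_policy {self.bh_policy!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        bad = set(raw) - known
        if bad:
            raise ValidationError(f"unknown run config keys: {sorted(bad)}")
        return cls(**raw)


@dataclass
class PipelineResult:
    fits: pd.DataFrame
    adjusted: pd.DataFrame
    assignments: list[CategoryAssignment]
    categories: pd.DataFrame
    mean_response: pd.DataFrame
    cv_results: pd.DataFrame
    summary: pd.DataFrame
    crosstab: pd.DataFrame
    orphans: list[str]
    mean_variance: pd.DataFrame
    age_summary: pd.DataFrame | None
    run_log: dict = field(default_factory=dict)


def fits_frame(fits: list[FitResult]) -> pd.DataFrame:
    cols = [
        "gene_id",
        "method",
        "slope",
        "intercept",
        "quad_coef",
        "r_squared",
        "p_slope_zero",
        "p_slope_one",
        "p_intercept_zero",
        "p_quad",
        "resid_normality_p",
        "resid_homoscedasticity_p",
        "degenerate",
        "n",
    ]
    return pd.DataFrame([{c: getattr(f, c) for c in cols} for f in fits])


def adjust_families(fits_df: pd.DataFrame, bh_policy: str = "per_family") -> pd.DataFrame:
    """BH-adjust the regression p-values across genes.

    ``per_family`` adjusts each test family on its own; ``global`` pools every
    available p-value into a single family.
    """
    out = fits_df[["gene_id"]].copy()
    if bh_policy == "per_family":
        for fam in TEST_FAMILIES:
            p = fits_df[fam].to_numpy(dtype=float)
            out[fam] = bh_adjust_masked(p)
    else:
        stacked = []
        for fam in TEST_FAMILIES:
            p = fits_df[fam].to_numpy(dtype=float)
            stacked.append(p)
        flat = np.concatenate(stacked)
        adj = bh_adjust_masked(flat)
        m = len(fits_df)
        for i, fam in enumerate(TEST_FAMILIES):
            out[fam] = adj[i * m : (i + 1) * m]
    return out


def run_pipeline(
    counts: CountMatrix, samples: SampleTable, config: RunConfig | None = None
) -> PipelineResult:
    """Run the full categorisation analysis on a validated count matrix."""
    cfg = config or RunConfig()
    n_genes_raw = counts.shape[0]

    counts = filter_unexpressed(counts, cfg.unexpressed_cpm)
    n_genes_expressed = counts.shape[0]
    if n_genes_expressed == 0:
        raise ValidationError("no genes survive the unexpressed filter")
    cpm = compute_cpm(counts)
    informative = filter_informative(cpm, samples, cfg.informative_cpm)
    if not informative:
        raise ValidationError("no informative genes above the cpm threshold")
    logger.info(
        "pipeline: %d genes, %d expressed, %d informative",
        n_genes_raw,
        n_genes_expressed,
        len(informative),
    )
    mv = mean_variance_profile(cpm)

    inds, base, stim = paired_matrices(cpm, samples, informative)
    profiles = pair_profiles(cpm, samples, informative)
    fits = [fit_gene(p, cfg.diagnostic_alpha, cfg.fallback_policy) for p in profiles]
    fits_df = fits_frame(fits)
    adjusted = adjust_families(fits_df, cfg.bh_policy)

    assignments = []
    for fit, (_, adj_row) in zip(fits, adjusted.iterrows()):
        adj = {fam: adj_row[fam] for fam in TEST_FAMILIES}
        if np.isnan(adj["p_quad"]):
            adj["p_quad"] = None
        assignments.append(assign_category(fit, adj, cfg.alpha))

    # paired mean-response check across the uncorrelated markers
    unc = [a.gene_id for a in assignments if "uncorrelated" in a.flags]
    by_gene = {p.gene_id: p for p in profiles}
    mean_rows = []
    if unc:
        raw = {g: paired_mean_test(by_gene[g]) for g in unc}
        p_adj = bh_adjust([raw[g][0] for g in unc])
        for g, adj_p in zip(unc, p_adj):
            p, hint = raw[g]
            direction = hint if adj_p <= cfg.alpha else "none"
            mean_rows.append(
                {"gene_id": g, "p": p, "p_adj": adj_p, "direction": direction}
            )
    mean_response = pd.DataFrame(
        mean_rows, columns=["gene_id", "p", "p_adj", "direction"]
    )
    mean_p = dict(zip(mean_response.get("gene_id", []), mean_response.get("p_adj", [])))
    for a in assignments:
        a.mean_response_p = mean_p.get(a.gene_id)

    cv_results = classify_variability(cv_test_genes(base, stim), cfg.alpha)
    summary = summarise_categories(assignments, cv_results)
    crosstab, orphans = cross_tabulate(assignments, cv_results)

    age_summary = None
    if "age_class" in samples.table.columns and samples.table["age_class"].notna().all():
        age = samples.age_class_of()
        class_sizes = age.value_counts()
        if all(class_sizes.get(c, 0) >= 3 for c in ("immature", "mature")):
            imm, mat = age_stratified_resample(
                base,
                stim,
                age,
                alpha=cfg.alpha,
                n_boot=cfg.n_boot,
                seed=seed_sequence(cfg.seed, "age_bootstrap"),
                draw_size=cfg.boot_draw_size,
            )
            age_summary = age_summary_frame([imm, mat], seed=cfg.seed)

    run_log = {
        "stimcat_version": __version__,
        "seed": cfg.seed,
        "config": asdict(cfg),
        "n_genes_input": int(n_genes_raw),
        "n_genes_expressed": int(n_genes_expressed),
        "n_genes_informative": len(informative),
        "n_individuals_paired": len(inds),
        "n_fallback_kendall_theil": int((fits_df["method"] == "kendall_theil").sum()),
    }
    return PipelineResult(
        fits=fits_df,
        adjusted=adjusted,
        assignments=assignments,
        categories=assignments_frame(assignments),
        mean_response=mean_response,
        cv_results=cv_results,
        summary=summary,
        crosstab=crosstab,
        orphans=orphans,
        mean_variance=mv,
        age_summary=age_summary,
        run_log=run_log,
    )


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_results(result: PipelineResult, outdir) -> None:
    """Write all stage tables, per-category gene lists and the run log."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    _write_tsv(result.fits, out / "fits.tsv")
    _write_tsv(result.adjusted, out / "adjusted_pvalues.tsv")
    _write_tsv(result.categories, out / "categories.tsv")
    _write_tsv(result.mean_response, out / "mean_response.tsv")
    _write_tsv(result.cv_results, out / "cv_tests.tsv")
    _write_tsv(result.summary, out / "summary.tsv")
    _write_tsv(result.crosstab, out / "crosstab.tsv")
    _write_tsv(result.mean_variance, out / "mean_variance.tsv")
    (out / "orphan_divergent.txt").write_text("".join(f"{g}\n" for g in result.orphans))
    if result.age_summary is not None:
        _write_tsv(result.age_summary, out / "age_summary.tsv")
    lists = out / "genelists"
    lists.mkdir(exist_ok=True)
    for cat in CATEGORIES:
        genes = sorted(a.gene_id for a in result.assignments if cat in a.flags)
        (lists / f"{cat}.txt").write_text("".join(f"{g}\n" for g in genes))
    with open(out / "run_log.yaml", "w") as fh:
        yaml.safe_dump(result.run_log, fh, sort_keys=True)
    # consistency check promised by the run log
    assert result.run_log["n_genes_informative"] == len(result.fits)


def correlate_platforms(x, y) -> tuple[float, float]:
    """Spearman rank correlation between two expression platforms (e.g. Q-PCR).

    Returns ``(rho, p)``; constant input leaves the rank correlation
    undefined and raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValidationError("correlate_platforms needs two equal-length vectors, n ≥ 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("rank correlation undefined for constant input")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def render_report(outdir, top_n: int = 10) -> str:
    """Render a markdown summary from a written results directory.

    Shows the category-count matrix (with convergent/divergent columns) and
    the top genes per category, ranked on R² (descending) with the adjusted
    slope-vs-zero p-value as tie-breaker.
    """
    out = Path(outdir)
    summary = pd.read_csv(out / "summary.tsv", sep="\t")
    categories = pd.read_csv(out / "categories.tsv", sep="\t")
    fits = pd.read_csv(out / "fits.tsv", sep="\t")
    merged = categories.merge(fits[["gene_id", "method", "r_squared"]], on="gene_id")

    lines = ["# Response-categorisation report", "", "## Category summary", ""]
    lines.append("| category | total | convergent | divergent |")
    lines.append("|---|---|---|---|")
    for _, row in summary.iterrows():
        lines.append(
            f"| {row['category']} | {row['total']} | {row['convergent']} | {row['divergent']} |"
        )
    lines += ["", "## Top markers per category (ranked on R², adjusted p tie-break)", ""]
    for cat in CATEGORIES:
        sub = merged[merged["flags"].str.contains(cat, regex=False)].copy()
        if sub.empty:
            continue
        sub["rank_p"] = sub.get("adj_p_slope_zero", np.nan)
        sub = sub.sort_values(["r_squared", "rank_p"], ascending=[False, True], na_position="last")
        top = ", ".join(sub["gene_id"].head(top_n))
        lines.append(f"- **{cat}**: {top}")
    if (out / "age_summary.tsv").exists():
        age = pd.read_csv(out / "age_summary.tsv", sep="\t")
        lines += ["", "## Age-stratified variability", ""]
        lines.append("| age class | direction | mean count | 95% interval | draws |")
        lines.append("|---|---|---|---|---|")
        for _, row in age.iterrows():
            lines.append(
                f"| {row['age_class']} | {row['direction']} | {row['mean_count']:.2f} "
                f"| [{row['ci_low']:.1f}, {row['ci_high']:.1f}] | {row['n_boot']} |"
            )
    return "\n".join(lines) + "\n"
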