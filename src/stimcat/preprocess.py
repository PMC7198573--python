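"""Count-matrix preprocessing: validation, cpm normalisation, expression filters,
and pairing of baseline/stimulated profiles per individual.

The pipeline starts from a featureCounts-style gene × sample table of raw read
counts plus a sample-metadata table mapping each sample to an individual and a
condition (``baseline`` or ``stimulated``). Counts are normalised to counts per
million (cpm) against library sizes recomputed from the genes currently in the
matrix, genes that never reach 3 cpm are dropped as unexpressed, and downstream
analysis is restricted to "informative" genes whose mean abundance exceeds
200 cpm in at least one condition — the region where the cpm mean–variance
relationship has flattened, so a gene's variance no longer tracks its mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("stimcat")

CONDITIONS = ("baseline", "stimulated")

#: Default cpm below which a gene is unexpressed if never exceeded in any sample.
UNEXPRESSED_CPM = 3.0
#: Default condition-wise mean cpm a gene must exceed to count as informative.
INFORMATIVE_CPM = 200.0


class StimcatError(Exception):
    """Base class for all package errors."""


class ParseError(StimcatError):
    """A file could not be parsed."""


class ValidationError(StimcatError):
    """Inputs violated a structural invariant."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Raw non-negative integer read counts, genes × samples.

    ``counts`` is a DataFrame indexed by gene id with one column per sample id.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            dupes = c.index[c.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dupes[:5]}")
        if c.columns.has_duplicates:
            dupes = c.columns[c.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dupes[:5]}")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if np.any(arr < 0):
            raise ValidationError("counts must be non-negative")
        if not np.allclose(arr, np.round(arr)):
            raise ValidationError("counts must be integers")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


@dataclass
class SampleTable:
    """Per-sample metadata: individual, condition, optional age class/sex/site."""

    table: pd.DataFrame

    REQUIRED = ("sample_id", "individual_id", "condition")
    AGE_CLASSES = ("immature", "mature")

    def __post_init__(self) -> None:
        t = self.table
        for col in self.REQUIRED:
            if col not in t.columns:
                raise ValidationError(f"metadata missing required column {col!r}")
        if t["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample_id in metadata")
        bad = set(t["condition"]) - set(CONDITIONS)
        if bad:
            raise ValidationError(
                f"condition must be one of {CONDITIONS}, got {sorted(bad)}"
            )
        dup = t.duplicated(subset=["individual_id", "condition"])
        if dup.any():
            pairs = t.loc[dup, ["individual_id", "condition"]].to_records(index=False)
            raise ValidationError(
                f"individual has more than one sample per condition: {list(pairs)[:5]}"
            )
        if "age_class" in t.columns:
            present = t["age_class"].dropna()
            bad = set(present) - set(self.AGE_CLASSES)
            if bad:
                raise ValidationError(
                    f"age_class must be one of {self.AGE_CLASSES}, got {sorted(bad)}"
                )
        self.table = t.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def samples_for(self, condition: str) -> list[str]:
        if condition not in CONDITIONS:
            raise ValidationError(f"unknown condition {condition!r}")
        t = self.table
        return list(t.loc[t["condition"] == condition, "sample_id"])

    def individuals(self) -> list[str]:
        """Individual ids in order of first appearance."""
        return list(dict.fromkeys(self.table["individual_id"]))

    def sample_of(self, individual: str, condition: str) -> str | None:
        t = self.table
        hit = t[(t["individual_id"] == individual) & (t["condition"] == condition)]
        if hit.empty:
            return None
        return hit["sample_id"].iloc[0]

    def age_class_of(self) -> pd.Series:
        """Age class per individual (index: individual_id)."""
        if "age_class" not in self.table.columns:
            raise ValidationError("metadata has no age_class column")
        t = self.table.dropna(subset=["age_class"])
        return t.groupby("individual_id", sort=False)["age_class"].first()


@dataclass
class CpmMatrix:
    """Counts-per-million matrix with the library sizes used to compute it."""

    cpm: pd.DataFrame
    library_sizes: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        if not self.cpm.columns.equals(self.library_sizes.index):
            raise ValidationError("library_sizes index must match cpm columns")
        colsums = self.cpm.sum(axis=0).to_numpy()
        if len(self.cpm) and not np.allclose(colsums, 1e6, rtol=1e-6):
            raise ValidationError("cpm columns must each sum to 1e6")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.cpm.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.cpm.columns)


@dataclass
class GeneResponseProfile:
    """Aligned baseline/stimulated cpm vectors across individuals for one gene."""

    gene_id: str
    individual_ids: np.ndarray
    cpm_base: np.ndarray
    cpm_stim: np.ndarray

    def __post_init__(self) -> None:
        self.individual_ids = np.asarray(self.individual_ids)
        self.cpm_base = np.asarray(self.cpm_base, dtype=float)
        self.cpm_stim = np.asarray(self.cpm_stim, dtype=float)
        n = len(self.individual_ids)
        if len(self.cpm_base) != n or len(self.cpm_stim) != n:
            raise ValidationError(f"{self.gene_id}: profile vectors of unequal length")

    @property
    def n(self) -> int:
        return len(self.individual_ids)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def read_counts(path, metadata_path) -> tuple[CountMatrix, SampleTable]:
    """Read a featureCounts-style TSV and a sample-metadata CSV/TSV.

    The counts file has a gene-id first column and one integer column per
    sample, with sample ids in the header. The metadata file must contain
    ``sample_id``, ``individual_id`` and ``condition`` columns; every sample in
    the counts header must be described.
    """
    try:
        raw = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pandas raises many flavours; wrap with the path
        raise ParseError(f"could not parse counts file {path}: {exc}") from exc
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)
    try:
        meta = pd.read_csv(metadata_path, sep=None, engine="python", dtype=str)
    except Exception as exc:
        raise ParseError(f"could not parse metadata file {metadata_path}: {exc}") from exc

    counts = CountMatrix(raw)
    samples = SampleTable(meta)
    missing = set(counts.sample_ids) - set(samples.sample_ids)
    if missing:
        raise ValidationError(
            f"samples present in counts but missing from metadata: {sorted(missing)[:5]}"
        )
    extra = set(samples.sample_ids) - set(counts.sample_ids)
    if extra:
        raise ValidationError(
            f"samples present in metadata but missing from counts: {sorted(extra)[:5]}"
        )
    return counts, samples


def compute_cpm(counts: CountMatrix) -> CpmMatrix:
    """Normalise to counts per million against column sums of the current matrix."""
    lib = counts.counts.sum(axis=0)
    zero = lib[lib <= 0]
    if len(zero):
        raise ValidationError(f"zero library size for samples: {list(zero.index)[:5]}")
    cpm = counts.counts.div(lib, axis=1) * 1e6
    return CpmMatrix(cpm=cpm.astype(float), library_sizes=lib.astype(int))


def filter_unexpressed(counts: CountMatrix, threshold: float = UNEXPRESSED_CPM) -> CountMatrix:
    """Drop genes whose cpm never reaches ``threshold`` in any sample.

    Library sizes are implicitly recalculated: downstream :func:`compute_cpm`
    always renormalises against the column sums of the genes that remain.
    """
    cpm = compute_cpm(counts).cpm
    keep = (cpm >= threshold).any(axis=1)
    removed = int((~keep).sum())
    if removed:
        logger.info("filter_unexpressed: removed %d genes below %.3g cpm", removed, threshold)
    return CountMatrix(counts.counts.loc[keep])


def filter_informative(
    cpm: CpmMatrix, samples: SampleTable, threshold: float = INFORMATIVE_CPM
) -> list[str]:
    """Genes with mean cpm strictly above ``threshold`` in either condition.

    Implements the and/or rule: a gene is informative if it is well expressed
    before stimulation, after it, or both.
    """
    if threshold <= 0:
        raise ValidationError("informative threshold must be positive")
    base_samples = samples.samples_for("baseline")
    stim_samples = samples.samples_for("stimulated")
    if not base_samples or not stim_samples:
        raise ValidationError("both conditions must be present to assess informativeness")
    mean_base = cpm.cpm[base_samples].mean(axis=1)
    mean_stim = cpm.cpm[stim_samples].mean(axis=1)
    keep = (mean_base > threshold) | (mean_stim > threshold)
    return list(cpm.cpm.index[keep])


def mean_variance_profile(cpm: CpmMatrix) -> pd.DataFrame:
    """Per-gene mean, sample variance (n−1) and CV of cpm across all samples.

    Used to locate the mean at which the CV–mean relationship asymptotes, which
    motivates the informative-cpm threshold.
    """
    if cpm.cpm.shape[1] < 2:
        raise ValidationError("mean-variance profile requires at least 2 samples")
    mean = cpm.cpm.mean(axis=1)
    var = cpm.cpm.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.sqrt(var) / mean
    return pd.DataFrame({"gene_id": cpm.cpm.index, "mean": mean, "variance": var, "cv": cv}).reset_index(
        drop=True
    )


def complete_individuals(samples: SampleTable) -> list[str]:
    """Individuals with both a baseline and a stimulated sample, in metadata order."""
    t = samples.table
    have = t.groupby("individual_id", sort=False)["condition"].agg(lambda c: set(c))
    complete = [ind for ind in samples.individuals() if have[ind] == set(CONDITIONS)]
    dropped = [ind for ind in samples.individuals() if ind not in complete]
    for ind in dropped:
        logger.warning("pair_profiles: dropping individual %s lacking one condition", ind)
    return complete


def paired_matrices(
    cpm: CpmMatrix, samples: SampleTable, genes: list[str] | None = None
) -> tuple[list[str], pd.DataFrame, pd.DataFrame]:
    """Gene × individual cpm matrices for baseline and stimulated conditions.

    Returns ``(individual_ids, base, stim)`` with identical gene and individual
    order in both matrices. Individuals lacking either condition are dropped.
    """
    if genes is None:
        genes = cpm.gene_ids
    if not genes:
        raise ValidationError("empty gene list")
    missing = set(genes) - set(cpm.gene_ids)
    if missing:
        raise ValidationError(f"genes not in cpm matrix: {sorted(missing)[:5]}")
    inds = complete_individuals(samples)
    if len(inds) < 3:
        raise ValidationError(
            f"only {len(inds)} individuals with both conditions; need at least 3"
        )
    base_cols = [samples.sample_of(i, "baseline") for i in inds]
    stim_cols = [samples.sample_of(i, "stimulated") for i in inds]
    base = cpm.cpm.loc[genes, base_cols]
    stim = cpm.cpm.loc[genes, stim_cols]
    base.columns = inds
    stim.columns = inds
    return inds, base, stim


def pair_profiles(
    cpm: CpmMatrix, samples: SampleTable, genes: list[str] | None = None
) -> list[GeneResponseProfile]:
    """One aligned baseline/stimulated profile per gene, shared individual order."""
    inds, base, stim = paired_matrices(cpm, samples, genes)
    ind_arr = np.asarray(inds)
    return [
        GeneResponseProfile(
            gene_id=g,
            individual_ids=ind_arr,
            cpm_base=base.loc[g].to_numpy(),
            cpm_stim=stim.loc[g].to_numpy(),
        )
        for g in base.index
    ]
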