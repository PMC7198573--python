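import numpy as np
import pandas as pd
import pytest

from stimcat import SimulationConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_counts(tmp_path):
    """A 3-gene × 4-sample counts TSV plus matching metadata, on disk."""
    counts = pd.DataFrame(
        {
            "s1": [100, 200, 700],
            "s2": [50, 150, 800],
            "s3": [120, 180, 700],
            "s4": [80, 220, 700],
        },
        index=pd.Index(["g1", "g2", "g3"], name="gene_id"),
    )
    meta = pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3", "s4"],
            "individual_id": ["i1", "i1", "i2", "i2"],
            "condition": ["baseline", "stimulated", "baseline", "stimulated"],
        }
    )
    cpath = tmp_path / "counts.tsv"
    mpath = tmp_path / "meta.csv"
    counts.to_csv(cpath, sep="\t")
    meta.to_csv(mpath, index=False)
    return cpath, mpath


@pytest.fixture(scope="session")
def small_dataset():
    """A small simulated cohort shared across tests (deterministic)."""
    cfg = SimulationConfig(
        genes_per_category={c: 8 for c in (
            "no_response", "uncorrelated", "constant",
            "baseline_dependent_linear", "baseline_dependent_quadratic")},
        n_convergent=4,
        n_divergent=4,
        seed=11,
    )
    counts, samples, truth = simulate_dataset(cfg)
    return cfg, counts, samples, truth
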