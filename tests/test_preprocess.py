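"""Preprocessing: I/O validation, cpm normalisation, filters, pairing."""

import numpy as np
import pandas as pd
import pytest

from stimcat import (
    CountMatrix,
    SampleTable,
    ParseError,
    ValidationError,
    read_counts,
    compute_cpm,
    filter_unexpressed,
    filter_informative,
    mean_variance_profile,
    pair_profiles,
)


def _count_matrix(arr, genes=None, samples=None):
    arr = np.asarray(arr)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return CountMatrix(pd.DataFrame(arr, index=genes, columns=samples))


def _sample_table(rows):
    return SampleTable(pd.DataFrame(rows, columns=["sample_id", "individual_id", "condition"]))


class TestReadCounts:
    def test_roundtrip(self, tiny_counts):
        counts, samples = read_counts(*tiny_counts)
        assert counts.shape == (3, 4)
        assert counts.gene_ids == ["g1", "g2", "g3"]
        assert samples.samples_for("baseline") == ["s1", "s3"]

    def test_bad_condition_value_rejected(self, tiny_counts, tmp_path):
        cpath, _ = tiny_counts
        bad = tmp_path / "bad_meta.csv"
        bad.write_text(
            "sample_id,individual_id,condition\n"
            "s1,i1,baseline\ns2,i1,stim\ns3,i2,baseline\ns4,i2,stimulated\n"
        )
        with pytest.raises(ValidationError, match="condition"):
            read_counts(cpath, bad)

    def test_duplicate_individual_condition_rejected(self, tiny_counts, tmp_path):
        cpath, _ = tiny_counts
        bad = tmp_path / "dup_meta.csv"
        bad.write_text(
            "sample_id,individual_id,condition\n"
            "s1,i1,baseline\ns2,i1,baseline\ns3,i2,baseline\ns4,i2,stimulated\n"
        )
        with pytest.raises(ValidationError, match="more than one sample"):
            read_counts(cpath, bad)

    def test_sample_missing_from_metadata(self, tiny_counts, tmp_path):
        cpath, _ = tiny_counts
        bad = tmp_path / "short_meta.csv"
        bad.write_text(
            "sample_id,individual_id,condition\n"
            "s1,i1,baseline\ns2,i1,stimulated\ns3,i2,baseline\n"
        )
        with pytest.raises(ValidationError, match="missing from metadata"):
            read_counts(cpath, bad)

    def test_malformed_counts_file(self, tmp_path, tiny_counts):
        _, mpath = tiny_counts
        bad = tmp_path / "bad.tsv"
        bad.write_text("gene\ts1\ng1\tnot_a_number_extra\tcolumn\n")
        with pytest.raises((ParseError, ValidationError)):
            read_counts(bad, mpath)

    def test_duplicate_gene_ids_rejected(self):
        df = pd.DataFrame([[1, 2], [3, 4]], index=["g1", "g1"], columns=["s1", "s2"])
        with pytest.raises(ValidationError, match="duplicate gene"):
            CountMatrix(df)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError, match="non-negative"):
            _count_matrix([[1, -2]])


class TestComputeCpm:
    def test_proportional_scaling(self):
        cm = _count_matrix([[250], [750]])
        cpm = compute_cpm(cm)
        assert cpm.cpm.iloc[:, 0].tolist() == [250000.0, 750000.0]
        assert cpm.library_sizes.iloc[0] == 1000

    def test_hand_arithmetic(self):
        cm = _count_matrix([[3], [1]])
        cpm = compute_cpm(cm)
        assert cpm.cpm.iloc[:, 0].tolist() == [750000.0, 250000.0]

    def test_zero_count_gene(self):
        cpm = compute_cpm(_count_matrix([[0], [10]]))
        assert cpm.cpm.iloc[0, 0] == 0.0

    def test_zero_library_errors(self):
        with pytest.raises(ValidationError, match="zero library"):
            compute_cpm(_count_matrix([[0, 5], [0, 5]]))

    def test_column_sums_are_one_million(self, rng):
        for _ in range(20):
            arr = rng.integers(0, 500, size=(15, 6)) + 1
            cpm = compute_cpm(_count_matrix(arr))
            np.testing.assert_allclose(cpm.cpm.sum(axis=0), 1e6, rtol=1e-6)


class TestFilterUnexpressed:
    def test_low_gene_removed_and_boundary_retained(self):
        # one sample with library size ~1e6 so cpm equals the count
        arr = np.zeros((3, 1), dtype=int)
        arr[0, 0] = 2  # max cpm < 3 -> removed
        arr[1, 0] = 3  # cpm 3 in one sample -> retained
        arr[2, 0] = 999_995
        out = filter_unexpressed(_count_matrix(arr))
        assert out.gene_ids == ["g1", "g2"]

    def test_identity_when_all_pass(self):
        cm = _count_matrix([[100, 200], [300, 400]])
        out = filter_unexpressed(cm)
        pd.testing.assert_frame_equal(out.counts, cm.counts)

    def test_idempotent(self, rng):
        arr = rng.integers(0, 1000, size=(30, 8))
        once = filter_unexpressed(_count_matrix(arr))
        twice = filter_unexpressed(once)
        pd.testing.assert_frame_equal(once.counts, twice.counts)


class TestFilterInformative:
    def test_or_of_condition_means(self):
        # gA informative at baseline only, gB nowhere; remaining mass in gC
        counts = _count_matrix(
            [[300, 320, 40, 50], [100, 90, 100, 110], [999_600, 999_590, 999_860, 999_840]],
            genes=["gA", "gB", "gC"],
        )
        samples = _sample_table(
            [["s0", "i1", "baseline"], ["s1", "i2", "baseline"],
             ["s2", "i1", "stimulated"], ["s3", "i2", "stimulated"]]
        )
        cpm = compute_cpm(counts)
        kept = filter_informative(cpm, samples, threshold=200)
        assert "gA" in kept and "gB" not in kept

    def test_strict_boundary(self):
        counts = _count_matrix([[200, 200], [999_800, 999_800]], genes=["gA", "gC"])
        samples = _sample_table([["s0", "i1", "baseline"], ["s1", "i1", "stimulated"]])
        kept = filter_informative(compute_cpm(counts), samples, threshold=200)
        assert "gA" not in kept  # mean exactly 200 is not strictly greater

    def test_nonpositive_threshold_rejected(self):
        counts = _count_matrix([[10, 10]])
        samples = _sample_table([["s0", "i1", "baseline"], ["s1", "i1", "stimulated"]])
        with pytest.raises(ValidationError):
            filter_informative(compute_cpm(counts), samples, threshold=0)

    def test_monotone_in_threshold(self, rng):
        arr = rng.integers(1, 2000, size=(40, 10))
        counts = _count_matrix(arr)
        samples = _sample_table(
            [[f"s{j}", f"i{j // 2}", "baseline" if j % 2 == 0 else "stimulated"]
             for j in range(10)]
        )
        cpm = compute_cpm(counts)
        previous = None
        for thr in (100, 500, 2000, 10000):
            kept = set(filter_informative(cpm, samples, threshold=thr))
            if previous is not None:
                assert kept <= previous
            previous = kept


class TestMeanVariance:
    def test_constant_gene(self):
        cpm = compute_cpm(_count_matrix([[5, 5, 5], [999_995, 999_995, 999_995]]))
        row = mean_variance_profile(cpm).iloc[0]
        assert row["variance"] == 0 and row["cv"] == 0

    def test_hand_values(self):
        # engineered so gene gA has cpm [2, 4]
        cpm = compute_cpm(_count_matrix([[2, 4], [999_998, 999_996]]))
        row = mean_variance_profile(cpm).iloc[0]
        assert row["mean"] == pytest.approx(3.0)
        assert row["variance"] == pytest.approx(2.0)
        assert row["cv"] == pytest.approx(np.sqrt(2) / 3, rel=1e-6)

    def test_single_sample_errors(self):
        cpm = compute_cpm(_count_matrix([[5]]))
        with pytest.raises(ValidationError):
            mean_variance_profile(cpm)


class TestPairProfiles:
    @staticmethod
    def _cohort(n_ind, missing_stim_for=()):
        rows, cols = [], []
        for i in range(n_ind):
            rows.append([f"b{i}", f"i{i}", "baseline"])
            cols.append(f"b{i}")
            if f"i{i}" not in missing_stim_for:
                rows.append([f"t{i}", f"i{i}", "stimulated"])
                cols.append(f"t{i}")
        counts = _count_matrix(
            np.arange(2 * len(cols)).reshape(2, -1) + 100, genes=["gA", "gB"], samples=cols
        )
        return compute_cpm(counts), _sample_table(rows)

    def test_complete_cohort(self):
        cpm, samples = self._cohort(5)
        profiles = pair_profiles(cpm, samples, ["gA", "gB"])
        assert all(p.n == 5 for p in profiles)
        assert list(profiles[0].individual_ids) == list(profiles[1].individual_ids)

    def test_incomplete_individual_dropped_with_warning(self, caplog):
        cpm, samples = self._cohort(5, missing_stim_for={"i2"})
        with caplog.at_level("WARNING", logger="stimcat"):
            profiles = pair_profiles(cpm, samples, ["gA"])
        assert profiles[0].n == 4
        assert any("i2" in r.message for r in caplog.records)

    def test_too_few_individuals(self):
        cpm, samples = self._cohort(2)
        with pytest.raises(ValidationError, match="at least 3"):
            pair_profiles(cpm, samples, ["gA"])

    def test_profiles_preserve_cpm_values_exactly(self):
        cpm, samples = self._cohort(4)
        profile = pair_profiles(cpm, samples, ["gB"])[0]
        for ind, b, s in zip(profile.individual_ids, profile.cpm_base, profile.cpm_stim):
            b_sample = samples.sample_of(ind, "baseline")
            s_sample = samples.sample_of(ind, "stimulated")
            assert b == cpm.cpm.loc["gB", b_sample]
            assert s == cpm.cpm.loc["gB", s_sample]
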