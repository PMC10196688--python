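"""Data containers, pseudo-count, clr transform and time-gap recurrence."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import microgen as mg
from microgen.datasets import MicrogenError, compute_time_gaps


def _write_cohort_files(tmp_path, table, meta_rows, taxonomy_rows):
    table_path = tmp_path / "otu.tsv"
    table.to_csv(table_path, sep="\t")
    meta_path = tmp_path / "meta.tsv"
    pd.DataFrame(meta_rows, columns=["sample_id", "subject_id", "timepoint"]).to_csv(
        meta_path, sep="\t", index=False)
    taxo_path = tmp_path / "taxo.tsv"
    pd.DataFrame(taxonomy_rows, columns=["taxon_id", "lineage"]).to_csv(
        taxo_path, sep="\t", index=False)
    return table_path, meta_path, taxo_path


class TestLoadDataset:
    def _basic_inputs(self, tmp_path, drop_sample=None, timepoints=(4, 7, 10)):
        rng = np.random.default_rng(0)
        samples, meta = [], []
        for subj in ("A", "B"):
            for t in timepoints:
                sid = f"{subj}_{t}"
                meta.append((sid, subj, t))
                samples.append(sid)
        if drop_sample is not None:
            samples.remove(drop_sample)
        counts = rng.integers(1, 100, size=(4, len(samples)))
        table = pd.DataFrame(counts, index=[f"OTU{i}" for i in range(4)],
                             columns=samples)
        taxo = [(f"OTU{i}", f"k__Bacteria; p__Phylum{i % 2}; c__X") for i in range(4)]
        return _write_cohort_files(tmp_path, table, meta, taxo)

    def test_absent_sample_gets_mask_zero(self, tmp_path):
        paths = self._basic_inputs(tmp_path, drop_sample="B_7")
        ds = mg.load_dataset(*paths)
        assert ds.mask.sum() == 5
        assert (ds.mask == 0).sum() == 1
        missing = np.argwhere(ds.mask == 0)[0]
        assert np.all(ds.abundances[missing[0], missing[1]] == 0)

    def test_count_columns_are_normalized(self, tmp_path):
        ds = mg.load_dataset(*self._basic_inputs(tmp_path))
        sums = ds.abundances[ds.mask == 1].sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_timepoints_sorted_ascending(self, tmp_path):
        ds = mg.load_dataset(*self._basic_inputs(tmp_path, timepoints=(10, 4, 7)))
        np.testing.assert_array_equal(ds.timepoints, [4.0, 7.0, 10.0])

    def test_phylum_parsed_from_lineage(self, tmp_path):
        ds = mg.load_dataset(*self._basic_inputs(tmp_path))
        assert set(ds.phylum) == {"Phylum0", "Phylum1"}

    def test_duplicate_subject_timepoint_rejected(self, tmp_path):
        table = pd.DataFrame(np.ones((2, 2)), index=["OTU0", "OTU1"],
                             columns=["s1", "s2"])
        paths = _write_cohort_files(
            tmp_path, table,
            [("s1", "A", 4), ("s2", "A", 4)],
            [("OTU0", "p__X"), ("OTU1", "p__X")])
        with pytest.raises(MicrogenError, match="duplicate"):
            mg.load_dataset(*paths)

    def test_unknown_taxon_named_in_error(self, tmp_path):
        table = pd.DataFrame(np.ones((2, 1)), index=["OTU0", "OTU9"],
                             columns=["s1"])
        paths = _write_cohort_files(tmp_path, table, [("s1", "A", 4)],
                                    [("OTU0", "p__X")])
        with pytest.raises(MicrogenError, match="OTU9"):
            mg.load_dataset(*paths)

    def test_zero_sum_column_rejected(self, tmp_path):
        table = pd.DataFrame(np.zeros((2, 1)), index=["OTU0", "OTU1"],
                             columns=["s1"])
        paths = _write_cohort_files(tmp_path, table, [("s1", "A", 4)],
                                    [("OTU0", "p__X"), ("OTU1", "p__X")])
        with pytest.raises(MicrogenError, match="s1"):
            mg.load_dataset(*paths)


def _dataset_from_tensor(x, mask=None, timepoints=None, phyla=None):
    x = np.asarray(x, dtype=float)
    s, k, n = x.shape
    return mg.LongitudinalDataset(
        abundances=x,
        timepoints=np.asarray(timepoints if timepoints is not None else np.arange(1, k + 1), dtype=float),
        mask=np.ones((s, k), dtype=int) if mask is None else np.asarray(mask),
        taxon_ids=[f"OTU{i}" for i in range(n)],
        phylum=list(phyla) if phyla is not None else ["P"] * n,
        subject_ids=[f"S{i}" for i in range(s)],
    )


class TestAddPseudocount:
    def test_hand_renormalization(self):
        # global min nonzero 0.1 -> c=0.05; (0.5, 0.5, 0) -> (0.5, 0.5, 0.05)/1.05
        ds = _dataset_from_tensor([[[0.5, 0.5, 0.0], [0.1, 0.4, 0.5]]])
        out = mg.add_pseudocount(ds)
        assert out.pseudo_count == pytest.approx(0.05)
        np.testing.assert_allclose(out.abundances[0, 0],
                                   [0.47619, 0.47619, 0.047619], atol=1e-5)
        np.testing.assert_allclose(out.abundances[0, 0, :2],
                                   [0.5 / 1.05] * 2, atol=1e-12)

    def test_positive_sample_only_renormalized(self):
        ds = _dataset_from_tensor([[[0.5, 0.3, 0.2], [0.6, 0.2, 0.2]]])
        out = mg.add_pseudocount(ds)
        np.testing.assert_allclose(out.abundances, ds.abundances, atol=1e-12)

    def test_minimum_is_global_over_samples(self):
        ds = _dataset_from_tensor([[[0.2, 0.8, 0.0], [0.02, 0.98, 0.0]]])
        out = mg.add_pseudocount(ds)
        assert out.pseudo_count == pytest.approx(0.01)

    def test_all_zero_dataset_rejected(self):
        ds = _dataset_from_tensor(np.zeros((1, 2, 3)),
                                  mask=np.zeros((1, 2), dtype=int))
        with pytest.raises(MicrogenError):
            mg.add_pseudocount(ds)

    def test_ranking_of_nonzero_abundances_preserved(self):
        rng = np.random.default_rng(5)
        x = rng.dirichlet(np.ones(8) * 0.5, size=(3, 4))
        x[x < 0.03] = 0
        x /= x.sum(axis=2, keepdims=True)
        ds = _dataset_from_tensor(x)
        out = mg.add_pseudocount(ds)
        for s in range(3):
            for t in range(4):
                nz = x[s, t] > 0
                before = np.argsort(x[s, t][nz])
                after = np.argsort(out.abundances[s, t][nz])
                np.testing.assert_array_equal(before, after)


class TestClrTransform:
    def test_uniform_composition_maps_to_zero(self):
        ds = _dataset_from_tensor([[[0.25, 0.25, 0.25, 0.25]]])
        ds.pseudo_count = 1e-3
        clr = mg.clr_transform(ds)
        np.testing.assert_allclose(clr.clr_values[0, 0], 0.0, atol=1e-12)

    def test_hand_computed_values(self):
        ds = _dataset_from_tensor([[[0.5, 0.25, 0.25]]])
        ds.pseudo_count = 1e-3
        clr = mg.clr_transform(ds)
        np.testing.assert_allclose(clr.clr_values[0, 0],
                                   [0.4621, -0.2310, -0.2310], atol=1e-4)

    def test_round_trip_recovers_composition(self, masked_cohort):
        clr = mg.clr_transform(mg.add_pseudocount(masked_cohort))
        obs = masked_cohort.mask == 1
        back = np.exp(clr.clr_values[obs])
        back /= back.sum(axis=1, keepdims=True)
        expected = mg.add_pseudocount(masked_cohort).abundances[obs]
        np.testing.assert_allclose(back, expected, atol=1e-9)

    def test_observed_samples_center_to_zero(self, clr_masked):
        obs = clr_masked.mask == 1
        sums = clr_masked.clr_values[obs].sum(axis=1)
        np.testing.assert_allclose(sums, 0.0, atol=1e-9)
        miss = clr_masked.mask == 0
        assert np.all(clr_masked.clr_values[miss] == 0)

    def test_nonpositive_entry_rejected(self):
        ds = _dataset_from_tensor([[[0.5, 0.5, 0.0]]])
        ds.pseudo_count = 1e-3
        with pytest.raises(MicrogenError):
            mg.clr_transform(ds)


def _gap_oracle(timepoints, mask_row):
    """Brute force: scan for the nearest observed index in each direction."""
    t = np.asarray(timepoints, dtype=float)
    e = np.asarray(mask_row)
    k = len(t)
    df = np.zeros(k)
    db = np.zeros(k)
    for i in range(1, k):
        prev = [j for j in range(i) if e[j] == 1]
        df[i] = t[i] - t[prev[-1]] if prev else t[i] - t[0] + df[0]
        if not prev:
            df[i] = t[i] - t[0]
    for i in range(k - 2, -1, -1):
        nxt = [j for j in range(i + 1, k) if e[j] == 1]
        db[i] = t[nxt[0]] - t[i] if nxt else t[-1] - t[i]
    return df, db


class TestTimeGaps:
    def test_printed_recurrence_example(self):
        df, db = compute_time_gaps([4, 7, 10, 13], [1, 0, 0, 1])
        np.testing.assert_array_equal(df, [0, 3, 6, 9])
        np.testing.assert_array_equal(db, [9, 6, 3, 0])

    def test_all_observed(self):
        df, db = compute_time_gaps([4, 7, 10], [1, 1, 1])
        np.testing.assert_array_equal(df, [0, 3, 3])
        np.testing.assert_array_equal(db, [3, 3, 0])

    def test_single_timepoint(self):
        df, db = compute_time_gaps([5.0], [1])
        np.testing.assert_array_equal(df, [0.0])
        np.testing.assert_array_equal(db, [0.0])

    def test_empty_rejected(self):
        with pytest.raises(MicrogenError):
            compute_time_gaps([], [])

    def test_matches_brute_force_oracle_on_random_masks(self):
        rng = np.random.default_rng(99)
        for _ in range(1000):
            k = int(rng.integers(1, 10))
            # integer-valued gaps keep both computations exact in float64
            t = np.cumsum(rng.integers(1, 5, size=k)).astype(float)
            e = rng.integers(0, 2, size=k)
            df, db = compute_time_gaps(t, e)
            odf, odb = _gap_oracle(t, e)
            np.testing.assert_array_equal(df, odf)
            np.testing.assert_array_equal(db, odb)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.integers(0, 1), min_size=1, max_size=12))
    def test_gaps_nonnegative_and_boundary_zero(self, mask_row):
        t = np.arange(1.0, len(mask_row) + 1.0)
        df, db = compute_time_gaps(t, mask_row)
        assert df[0] == 0 and db[-1] == 0
        assert np.all(df >= 0) and np.all(db >= 0)
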