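"""Tanimoto clustering, dendrogram cutting and benchmark-series construction."""

import numpy as np
import pytest

from helpers import average_linkage_oracle, clusters_at_threshold_oracle, tanimoto_direct
from pharmnet import (
    DEFAULT_THRESHOLDS,
    InteractionDataset,
    ProfileMatrix,
    average_linkage,
    build_series,
    cut_and_select,
    tanimoto,
)


def _random_fp(rng, n, bits=12, density=0.4, prefix="d"):
    arr = (rng.random((n, bits)) < density).astype(int)
    arr[arr.sum(axis=1) == 0, 0] = 1  # no empty fingerprints
    return ProfileMatrix.from_dense(
        [f"{prefix}{i:02d}" for i in range(n)],
        [f"b{j}" for j in range(bits)],
        arr,
    )


class TestTanimoto:
    def test_identical_nonzero_is_one(self):
        assert tanimoto([1, 0, 1], [1, 0, 1]) == 1.0

    def test_disjoint_is_zero(self):
        assert tanimoto([1, 0, 0], [0, 1, 1]) == 0.0

    def test_partial_overlap(self):
        # on-bits {1,2,3} vs {2,3,4}: 2 shared of 4 in the union
        assert tanimoto([0, 1, 1, 1, 0], [0, 0, 1, 1, 1]) == 0.5

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            tanimoto([1, 0], [1, 0, 1])

    def test_both_empty_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="empty"):
            assert tanimoto([0, 0], [0, 0]) == 0.0

    def test_symmetric_and_one_iff_equal(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            a = rng.integers(0, 2, size=10)
            b = rng.integers(0, 2, size=10)
            if not a.any() or not b.any():
                continue
            assert tanimoto(a, b) == tanimoto(b, a)
            assert (tanimoto(a, b) == 1.0) == bool((a == b).all())
            assert np.isclose(tanimoto(a, b), tanimoto_direct(a, b))


class TestAverageLinkage:
    def test_identical_pair_merges_at_one(self):
        fp = ProfileMatrix.from_dense(["a", "b"], ["x", "y"], np.array([[1, 1], [1, 1]]))
        dend = average_linkage(fp)
        assert len(dend.merges) == 1
        assert dend.merges[0][2] == 1.0

    def test_all_dissimilar_merge_at_zero(self):
        fp = ProfileMatrix.from_dense(
            ["a", "b", "c"], ["x", "y", "z"], np.eye(3, dtype=int)
        )
        dend = average_linkage(fp)
        assert [m[2] for m in dend.merges] == [0.0, 0.0]

    def test_fewer_than_two_entities_rejected(self):
        fp = ProfileMatrix.from_dense(["a"], ["x"], np.array([[1]]))
        with pytest.raises(ValueError):
            average_linkage(fp)

    def test_merge_similarity_non_increasing(self):
        fp = _random_fp(np.random.default_rng(2), 10)
        heights = [m[2] for m in average_linkage(fp).merges]
        assert all(a >= b - 1e-12 for a, b in zip(heights, heights[1:]))

    def test_heights_match_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            fp = _random_fp(rng, 6)
            got = [m[2] for m in average_linkage(fp).merges]
            want = average_linkage_oracle(fp)
            assert np.allclose(got, want, atol=1e-9)


class TestCutAndSelect:
    def _setup(self):
        rng = np.random.default_rng(9)
        fp = _random_fp(rng, 8)
        ds = InteractionDataset.build(
            fp.entity_ids, ["p1", "p2"],
            [("d00", "p1"), ("d00", "p2"), ("d01", "p1"), ("d05", "p2")],
        )
        return fp, ds

    def test_threshold_one_keeps_distinct_drugs_apart(self):
        fp, ds = self._setup()
        dend = average_linkage(fp)
        clusters, reps = cut_and_select(dend, 1.0, ds)
        # no two fingerprints identical in this draw: everyone survives
        assert len(reps) == fp.n_entities

    def test_threshold_below_all_merges_single_cluster(self):
        fp, ds = self._setup()
        dend = average_linkage(fp)
        clusters, reps = cut_and_select(dend, 1e-9, ds)
        assert len(clusters) == 1
        assert len(reps) == 1
        assert reps[0] == "d00"  # most interactions wins representative choice

    def test_one_representative_per_cluster(self):
        fp, ds = self._setup()
        dend = average_linkage(fp)
        for t in (0.2, 0.5, 0.8):
            clusters, reps = cut_and_select(dend, t, ds)
            assert len(clusters) == len(reps)
            for c, r in zip(clusters, reps):
                assert r in c

    def test_representative_ties_break_lexicographically(self):
        fp = ProfileMatrix.from_dense(
            ["dB", "dA"], ["x", "y"], np.array([[1, 1], [1, 1]])
        )
        ds = InteractionDataset.build(["dB", "dA"], ["p"], [("dB", "p"), ("dA", "p")])
        _, reps = cut_and_select(average_linkage(fp), 0.5, ds)
        assert reps == ["dA"]

    def test_threshold_out_of_range_rejected(self):
        fp, ds = self._setup()
        dend = average_linkage(fp)
        with pytest.raises(ValueError):
            cut_and_select(dend, 0.0, ds)
        with pytest.raises(ValueError):
            cut_and_select(dend, 1.5, ds)

    def test_membership_matches_from_scratch_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(3):
            fp = _random_fp(rng, 7)
            ds = InteractionDataset.build(fp.entity_ids, ["p"], [(fp.entity_ids[0], "p")])
            dend = average_linkage(fp)
            for t in (0.3, 0.6, 0.9):
                clusters, _ = cut_and_select(dend, t, ds)
                got = {frozenset(c) for c in clusters}
                assert got == clusters_at_threshold_oracle(fp, t)


class TestBuildSeries:
    def _inputs(self, seed=3, n=12):
        rng = np.random.default_rng(seed)
        fp = _random_fp(rng, n)
        positives = {
            (d, f"p{j}")
            for d in fp.entity_ids
            for j in range(3)
            if rng.random() < 0.4
        }
        positives.add((fp.entity_ids[0], "p0"))
        ds = InteractionDataset.build(fp.entity_ids, [f"p{j}" for j in range(3)], positives)
        return ds, fp

    def test_default_thresholds_give_nine_benchmarks(self):
        ds, fp = self._inputs()
        series = build_series(ds, fp)
        assert len(series.thresholds) == 9
        assert len(series.datasets) == 9

    def test_benchmark_drugs_subset_of_original(self):
        ds, fp = self._inputs()
        series = build_series(ds, fp)
        for t in series.thresholds:
            assert set(series.datasets[t].drug_ids) <= set(ds.drug_ids)
            assert series.datasets[t].protein_ids == ds.protein_ids

    def test_representative_count_non_decreasing_in_threshold(self):
        for seed in range(5):
            ds, fp = self._inputs(seed=seed)
            series = build_series(ds, fp)
            counts = [len(series.representatives[t]) for t in series.thresholds]
            assert counts == sorted(counts)

    def test_empty_threshold_list_rejected(self):
        ds, fp = self._inputs()
        with pytest.raises(ValueError):
            build_series(ds, fp, thresholds=())

    def test_warns_when_fewer_drugs_than_folds(self):
        fp = ProfileMatrix.from_dense(
            ["d1", "d2"], ["x", "y"], np.array([[1, 0], [1, 0]])
        )
        ds = InteractionDataset.build(["d1", "d2"], ["p"], [("d1", "p")])
        with pytest.warns(UserWarning, match="representative drugs"):
            build_series(ds, fp, thresholds=(0.5,))

    def test_summary_table_shape(self):
        ds, fp = self._inputs()
        series = build_series(ds, fp)
        s = series.summary()
        assert list(s.columns) == ["threshold", "n_clusters", "n_drugs", "n_positives"]
        assert len(s) == len(DEFAULT_THRESHOLDS)
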