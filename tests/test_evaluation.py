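"""ROC/AUC statistic and the pair-wise / block-wise CV protocols."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import auc_pair_counting
from pharmnet import (
    DescriptorSpec,
    FitConfig,
    InteractionDataset,
    SimConfig,
    generate,
    make_folds,
    roc_auc,
    run_blockwise_cv,
    run_pairwise_cv,
)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, -1, -1]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([0.3, 0.3, 0.3, 0.3], [1, 1, -1, -1]) == 0.5

    def test_two_of_four_concordant(self):
        # frozen by pair counting: of the 4 pos-neg pairs, 2 are concordant
        assert roc_auc([0.9, 0.4, 0.8, 0.5], [1, 1, -1, -1]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_matches_pair_counting_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = rng.integers(4, 40)
            scores = rng.choice([0.1, 0.25, 0.5, 0.9], size=n)  # force ties
            labels = np.where(rng.random(n) < 0.5, 1, -1)
            if len(np.unique(labels)) < 2:
                continue
            assert abs(roc_auc(scores, labels) - auc_pair_counting(scores, labels)) < 1e-12

    @given(st.data())
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_invariant_under_monotone_transform(self, data):
        n = data.draw(st.integers(4, 25))
        # quantized scores keep affine transforms strictly monotone in fp arithmetic
        scores = np.array(data.draw(
            st.lists(st.integers(-50, 50), min_size=n, max_size=n))) / 10.0
        labels = np.array(data.draw(
            st.lists(st.sampled_from([-1, 1]), min_size=n, max_size=n)))
        if len(np.unique(labels)) < 2:
            return
        base = roc_auc(scores, labels)
        assert np.isclose(roc_auc(3.0 * scores + 7.0, labels), base)
        assert np.isclose(roc_auc(np.exp(scores / 5.0), labels), base)

    def test_complement_symmetry_without_ties(self):
        rng = np.random.default_rng(1)
        scores = rng.permutation(20).astype(float)  # all distinct
        labels = np.where(rng.random(20) < 0.4, 1, -1)
        assert np.isclose(roc_auc(-scores, labels), 1.0 - roc_auc(scores, labels))


class TestMakeFolds:
    def _dataset(self, n_d=5, n_p=2):
        return InteractionDataset.build(
            [f"d{i}" for i in range(n_d)],
            [f"p{j}" for j in range(n_p)],
            [("d0", "p0")],
        )

    def test_pairwise_fold_sizes_balanced(self):
        ds = self._dataset()  # 10 pairs
        fa = make_folds(ds, "pairwise", n_folds=5, seed=0)
        sizes = np.bincount(fa.pair_folds, minlength=5)
        assert sizes.tolist() == [2, 2, 2, 2, 2]

    def test_same_seed_reproduces_assignment(self):
        ds = self._dataset(8, 6)
        a = make_folds(ds, "pairwise", seed=42)
        b = make_folds(ds, "pairwise", seed=42)
        assert np.array_equal(a.pair_folds, b.pair_folds)
        c = make_folds(ds, "blockwise", seed=42)
        d = make_folds(ds, "blockwise", seed=42)
        assert c.drug_folds == d.drug_folds and c.protein_folds == d.protein_folds

    def test_blockwise_partitions_cover_and_balance(self):
        ds = self._dataset(10, 10)
        fa = make_folds(ds, "blockwise", n_folds=5, seed=3)
        for mapping, ids in ((fa.drug_folds, ds.drug_ids), (fa.protein_folds, ds.protein_ids)):
            assert set(mapping) == set(ids)
            sizes = np.bincount(list(mapping.values()), minlength=5)
            assert sizes.max() - sizes.min() <= 1

    def test_blockwise_streams_are_independent(self):
        ds = self._dataset(30, 30)
        fa = make_folds(ds, "blockwise", n_folds=5, seed=3)
        drug_seq = [fa.drug_folds[d] for d in ds.drug_ids]
        prot_seq = [fa.protein_folds[p] for p in ds.protein_ids]
        assert drug_seq != prot_seq  # distinct sub-seeds

    def test_too_many_folds_rejected(self):
        ds = self._dataset(3, 2)
        with pytest.raises(ValueError):
            make_folds(ds, "blockwise", n_folds=4, seed=0)


STRONG = SimConfig(
    n_drugs=40,
    n_proteins=30,
    n_side_effects=15,
    n_domains=10,
    n_planted=4,
    effect_size=8.0,
    label_noise=0.0,
    se_density=0.2,
    domain_density=0.15,
    n_lead_series=5,
    seed=11,
)


class TestPairwiseCV:
    def test_every_pair_scored_once(self, sim_small):
        data = sim_small
        spec = DescriptorSpec.for_profiles("tensor", data.side_effects, data.domains)
        r = run_pairwise_cv(
            data.interactions, data.side_effects, data.domains, spec,
            FitConfig(penalty="L1", C=1.0), seed=2,
        )
        assert len(r.scores["pairwise"]) == data.interactions.n_pairs
        assert sum(m["n_test"] for m in r.fold_metadata) == data.interactions.n_pairs

    def test_strong_planted_signal_gives_high_auc(self):
        # the intercept soaks up the ~95% negative base rate; without it the
        # no-bias objective pushes frequent cells negative and the ranking
        # partly reflects descriptor support size rather than the signal
        data = generate(STRONG)
        spec = DescriptorSpec.for_profiles("tensor", data.side_effects, data.domains)
        r = run_pairwise_cv(
            data.interactions, data.side_effects, data.domains, spec,
            FitConfig(penalty="L1", C=1.0, intercept=True), seed=11,
        )
        assert r.aucs["pairwise"] >= 0.9

    def test_permuted_labels_are_null(self):
        data = generate(STRONG)
        rng = np.random.default_rng(99)
        y = data.interactions.label_matrix().ravel()
        rng.shuffle(y)
        pairs = [(d, p) for d in data.interactions.drug_ids
                 for p in data.interactions.protein_ids]
        ds = InteractionDataset.build(
            data.interactions.drug_ids,
            data.interactions.protein_ids,
            {pairs[i] for i in np.flatnonzero(y > 0)},
        )
        spec = DescriptorSpec.for_profiles("tensor", data.side_effects, data.domains)
        r = run_pairwise_cv(ds, data.side_effects, data.domains, spec,
                            FitConfig(penalty="L1", C=1.0), seed=11)
        assert abs(r.aucs["pairwise"] - 0.5) <= 0.1


class TestBlockwiseCV:
    @pytest.fixture(scope="class")
    def blockwise_run(self):
        data = generate(STRONG)
        spec = DescriptorSpec.for_profiles("tensor", data.side_effects, data.domains)
        folds = make_folds(data.interactions, "blockwise", seed=11)
        result = run_blockwise_cv(
            data.interactions, data.side_effects, data.domains, spec,
            FitConfig(penalty="L1", C=1.0), folds=folds,
        )
        return data, folds, result

    def test_category_universes_disjoint_and_counted(self, blockwise_run):
        data, folds, r = blockwise_run
        df, pf = folds.drug_folds, folds.protein_folds
        n_same = sum(
            1 for d in data.interactions.drug_ids
            for p in data.interactions.protein_ids if df[d] == pf[p]
        )
        n_diff = data.interactions.n_pairs - n_same
        # pairs with equal folds are scored once (TestDrug-TestProtein);
        # the rest once in each asymmetric category
        assert len(r.scores["TestDrug-TestProtein"]) == n_same
        assert len(r.scores["TestDrug-TrainProtein"]) == n_diff
        assert len(r.scores["TrainDrug-TestProtein"]) == n_diff

    def test_aucs_within_unit_interval(self, blockwise_run):
        _, _, r = blockwise_run
        for auc in r.aucs.values():
            assert 0.0 <= auc <= 1.0

    def test_pairwise_at_least_blockwise_on_strong_signal(self, blockwise_run):
        data, _, bw = blockwise_run
        spec = DescriptorSpec.for_profiles("tensor", data.side_effects, data.domains)
        pw = run_pairwise_cv(
            data.interactions, data.side_effects, data.domains, spec,
            FitConfig(penalty="L1", C=1.0), seed=11,
        )
        assert pw.aucs["pairwise"] >= bw.aucs["TestDrug-TestProtein"] - 0.05

    def test_summary_serialises(self, blockwise_run, tmp_path):
        _, _, r = blockwise_run
        r.save_tsv(tmp_path / "cv.tsv")
        frame = r.to_frame()
        assert set(frame.category) == set(r.aucs)
        assert (tmp_path / "cv.tsv").read_text().startswith("category\t")
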