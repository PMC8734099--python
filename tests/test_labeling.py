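import numpy as np
import pytest

from degsign.io import DifferentialTable, ExpressionDataset
from degsign.labeling import (build_features, compute_de_standin, label_genes,
                              make_cv_folds, make_split, quantile_filter)

from conftest import random_labeled_set


def _dataset(matrix, conditions, gene_ids=None):
    matrix = np.asarray(matrix, dtype=float)
    return ExpressionDataset(
        gene_ids=gene_ids or [f"g{i}" for i in range(matrix.shape[0])],
        matrix=matrix,
        sample_ids=[f"s{j}" for j in range(matrix.shape[1])],
        conditions=np.array(conditions, dtype=object),
        name="unit",
    )


class TestDeStandin:
    def test_equal_means_give_zero_logfc(self):
        ds = _dataset([[5, 7, 5, 7]], ["normal", "normal", "tumor", "tumor"])
        de = compute_de_standin(ds)
        assert de.logfc[0] == pytest.approx(0.0)

    def test_logfc_formula(self):
        # tumor mean 31, normal mean 7, pseudocount 1 -> log2(32/8) = 2
        ds = _dataset([[7, 7, 31, 31]], ["normal", "normal", "tumor", "tumor"])
        de = compute_de_standin(ds, pseudocount=1.0)
        assert de.logfc[0] == pytest.approx(2.0)

    def test_benjamini_hochberg_step_up(self, monkeypatch):
        # p-values (0.01, 0.02, 0.03) over 3 genes -> fdr (0.03, 0.03, 0.03):
        # step-up from the largest p keeps min(p*k/rank) = 0.03 for all
        ds = _dataset(np.ones((3, 4)), ["normal", "normal", "tumor", "tumor"])
        from scipy import stats

        class FakeRes:
            pvalue = np.array([0.01, 0.02, 0.03])

        monkeypatch.setattr(stats, "ttest_ind", lambda *a, **k: FakeRes())
        de = compute_de_standin(ds)
        np.testing.assert_allclose(de.fdr, [0.03, 0.03, 0.03])

    def test_requires_two_samples_per_condition(self):
        ds = _dataset([[1, 2, 3]], ["normal", "tumor", "tumor"])
        with pytest.raises(ValueError, match="2 samples"):
            compute_de_standin(ds)


class TestLabelGenes:
    @pytest.fixture
    def four_sample_dataset(self):
        rng = np.random.default_rng(0)
        return _dataset(rng.integers(1, 100, size=(4, 4)),
                        ["normal", "normal", "tumor", "tumor"],
                        gene_ids=["gA", "gB", "gC", "gD"])

    @pytest.mark.parametrize("logfc,fdr,expected", [
        (-1.2, 0.001, 0),   # significant, negative -> down
        (0.8, 0.5, 2),      # not significant -> neutral
        (2.1, 0.004, 1),    # significant, positive -> up
        (0.0, 0.001, 2),    # exact threshold stays neutral (strict sign rule)
    ])
    def test_sign_and_significance_rules(self, four_sample_dataset, logfc,
                                         fdr, expected):
        de = DifferentialTable(gene_ids=["gA", "gB", "gC", "gD"],
                               logfc=[logfc, 1, 1, 1],
                               fdr=[fdr, 0.5, 0.5, 0.5])
        labeled = label_genes(four_sample_dataset, de)
        assert labeled.labels[0] == expected

    def test_bio_flag_requires_significance(self, four_sample_dataset):
        de = DifferentialTable(gene_ids=["gA", "gB", "gC", "gD"],
                               logfc=[2.1, -1.0, 1.0, 1.0],
                               fdr=[0.004, 0.5, 0.5, 0.5])
        labeled = label_genes(four_sample_dataset, de, bio={"gA", "gB"})
        assert labeled.labels[0] == 1 and labeled.bio_flags[0]
        # gB is in the list but not significant: neutral, not bio-validated
        assert labeled.labels[1] == 2 and not labeled.bio_flags[1]

    def test_genes_missing_from_de_table_dropped(self, four_sample_dataset):
        de = DifferentialTable(gene_ids=["gA", "gC"], logfc=[1.0, -1.0],
                               fdr=[0.001, 0.001])
        labeled = label_genes(four_sample_dataset, de)
        assert labeled.gene_ids == ["gA", "gC"]
        assert labeled.meta["dropped_genes"] == 2

    def test_empty_intersection_is_error(self, four_sample_dataset):
        de = DifferentialTable(gene_ids=["zz"], logfc=[1.0], fdr=[0.001])
        with pytest.raises(ValueError, match="no overlap"):
            label_genes(four_sample_dataset, de)

    def test_label_conservation(self, four_sample_dataset):
        de = DifferentialTable(gene_ids=["gA", "gB", "gC", "gD"],
                               logfc=[2.0, -2.0, 0.5, 1.0],
                               fdr=[0.001, 0.001, 0.5, 0.005])
        labeled = label_genes(four_sample_dataset, de)
        counts = np.bincount(labeled.labels, minlength=3)
        assert counts.sum() == labeled.n_genes


class TestBuildFeatures:
    def test_interleaves_conditions(self):
        ds = _dataset([[1, 2, 3, 4]], ["normal", "tumor", "normal", "tumor"])
        _, order = build_features(ds)
        # balanced design: normal, tumor, normal, tumor by rank fraction
        assert [ds.conditions[i] for i in order] == [
            "normal", "tumor", "normal", "tumor"]

    def test_per_gene_standardization(self):
        rng = np.random.default_rng(1)
        ds = _dataset(rng.integers(1, 1000, size=(5, 8)),
                      ["normal"] * 4 + ["tumor"] * 4)
        feats, _ = build_features(ds)
        np.testing.assert_allclose(feats.mean(axis=1), 0.0, atol=1e-5)
        np.testing.assert_allclose(feats.std(axis=1), 1.0, atol=1e-5)

    def test_constant_gene_maps_to_zeros(self):
        ds = _dataset([[5, 5, 5, 5]], ["normal", "normal", "tumor", "tumor"])
        feats, _ = build_features(ds)
        np.testing.assert_array_equal(feats, 0.0)


class TestMakeSplit:
    def test_ratio_arithmetic(self):
        rng = np.random.default_rng(2)
        labels = random_labeled_set(rng, n_genes=150, min_per_class=30,
                                    min_bio_per_class=25)
        split = make_split(labels, seed=3)
        assert len(split.T1) + len(split.T2) == 100
        assert len(split.F1) + len(split.T3) == 50
        assert len(split.T1) == 80 and len(split.F1) == 40

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(3)
        labels = random_labeled_set(rng)
        a = make_split(labels, seed=11)
        b = make_split(labels, seed=11)
        for part in ("T1", "T2", "F1", "T3"):
            np.testing.assert_array_equal(getattr(a, part), getattr(b, part))

    def test_stratified_allocation(self):
        # Q with 30 up + 20 down -> F1 holds 24 up + 16 down (+-1)
        n = 150
        labels_arr = np.array([1] * 30 + [0] * 20 + [2] * 100)
        bio = np.array([True] * 50 + [False] * 100)
        from degsign.labeling import LabeledGeneSet
        labels = LabeledGeneSet(
            gene_ids=[f"G{i}" for i in range(n)],
            features=np.zeros((n, 8), dtype=np.float32),
            labels=labels_arr, bio_flags=bio, name="strat")
        split = make_split(labels, seed=0)
        f1_labels = labels.labels[split.F1]
        assert abs(int(np.sum(f1_labels == 1)) - 24) <= 1
        assert abs(int(np.sum(f1_labels == 0)) - 16) <= 1

    def test_small_bio_partition_rejected(self):
        from degsign.labeling import LabeledGeneSet
        labels = LabeledGeneSet(
            gene_ids=[f"G{i}" for i in range(20)],
            features=np.zeros((20, 8), dtype=np.float32),
            labels=np.array([0, 1] * 10),
            bio_flags=np.array([True] * 4 + [False] * 16),
            name="smallq")
        with pytest.raises(ValueError, match="at least 5"):
            make_split(labels, seed=0)


class TestMakeCvFolds:
    def test_fold_sizes_and_partition(self):
        labels = np.array([0] * 40 + [1] * 30 + [2] * 30)
        indices = np.arange(100)
        folds = make_cv_folds(labels, indices, k=5, seed=1)
        assert [len(f) for f in folds] == [20] * 5
        union = np.sort(np.concatenate(folds))
        np.testing.assert_array_equal(union, indices)
        for i in range(5):
            for j in range(i + 1, 5):
                assert len(np.intersect1d(folds[i], folds[j])) == 0

    def test_seed_changes_assignment_not_sizes(self):
        labels = np.array([0] * 40 + [1] * 40 + [2] * 20)
        indices = np.arange(100)
        a = make_cv_folds(labels, indices, k=5, seed=1)
        b = make_cv_folds(labels, indices, k=5, seed=2)
        assert [len(f) for f in a] == [len(f) for f in b]
        assert any(not np.array_equal(x, y) for x, y in zip(a, b))

    def test_class_smaller_than_k_rejected(self):
        labels = np.array([0] * 3 + [1] * 50)
        with pytest.raises(ValueError, match="cannot form"):
            make_cv_folds(labels, np.arange(53), k=5, seed=0)


class TestQuantileFilter:
    def test_quantile_cutoff(self):
        # per-gene means (1, 2, 3, 4); 0.25-quantile = 1.75 -> 3 genes retained
        ds = _dataset([[1, 1], [2, 2], [3, 3], [4, 4]], ["normal", "tumor"])
        out = quantile_filter(ds, q=0.25)
        assert out.n_genes == 3
        assert out.gene_ids == ["g1", "g2", "g3"]

    def test_small_q_keeps_everything_above_the_minimum(self):
        # cutoff tends to the minimum mean as q -> 0; the strict rule keeps
        # every gene whose mean exceeds it
        ds = _dataset([[1, 1], [2, 2], [3, 3], [4, 4]], ["normal", "tumor"])
        out = quantile_filter(ds, q=1e-9)
        assert out.gene_ids == ["g1", "g2", "g3"]

    def test_constant_matrix_rejected(self):
        ds = _dataset(np.full((4, 2), 7.0), ["normal", "tumor"])
        with pytest.raises(ValueError, match="every gene"):
            quantile_filter(ds, q=0.25)

    def test_invalid_q_rejected(self):
        ds = _dataset([[1, 1]], ["normal", "tumor"])
        with pytest.raises(ValueError, match="q must be"):
            quantile_filter(ds, q=1.5)
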