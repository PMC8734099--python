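import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import _oracles as oracle
from degsign.evaluation import (MetricsReport, add_gaussian_noise,
                                compute_metrics, read_metrics_report,
                                robustness_curve, run_baselines,
                                write_metrics_report, write_roc_points)
from degsign.model import GeneClassifierCNN, ModelConfig

SMALL = dict(conv_channels=(2, 2, 3, 3, 4, 4, 5, 5), linear_widths=(5, 4, 4, 3))


class TestComputeMetrics:
    def test_perfect_binary_predictions(self):
        y = np.array([0, 1, 0, 1, 1])
        m = compute_metrics(y, y, scores=y.astype(float))
        assert m["accuracy"] == 100.0
        assert m["mcc"] == pytest.approx(1.0)
        assert m["f_measure"] == pytest.approx(1.0)
        assert m["roc_auc"] == pytest.approx(1.0)

    def test_known_binary_confusion_matrix(self):
        # TP=40, TN=40, FP=10, FN=10 -> MCC = (1600-100)/2500 = 0.6
        y_true = np.array([1] * 50 + [0] * 50)
        y_pred = np.array([1] * 40 + [0] * 10 + [1] * 10 + [0] * 40)
        m = compute_metrics(y_true, y_pred)
        assert m["mcc"] == pytest.approx(0.6)
        assert m["accuracy"] == pytest.approx(80.0)

    def test_random_scores_chance_auc(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, size=10000)
        scores = rng.uniform(size=10000)
        m = compute_metrics(y, y, scores=scores)
        assert m["roc_auc"] == pytest.approx(0.5, abs=0.05)

    def test_single_class_truth_gives_nan_roc(self):
        y = np.zeros(5, dtype=int)
        m = compute_metrics(y, y, scores=np.zeros(5))
        assert np.isnan(m["roc_auc"])
        assert m["accuracy"] == 100.0  # no exception raised

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([0, 1], [0])

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 2), st.integers(0, 2)),
                    min_size=1, max_size=60))
    def test_accuracy_equals_weighted_recall(self, pairs):
        """Support-weighted recall is the confusion-matrix trace over its
        total, i.e. exactly the accuracy — for any label vectors."""
        y_true = np.array([t for t, _ in pairs])
        y_pred = np.array([p for _, p in pairs])
        m = compute_metrics(y_true, y_pred)
        assert m["accuracy"] == pytest.approx(m["recall"], abs=1e-9)
        assert 0 <= m["accuracy"] <= 100
        assert -1 <= m["mcc"] <= 1

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            k = int(rng.integers(2, 4))
            n = int(rng.integers(10, 60))
            y_true = rng.integers(0, k, size=n)
            while len(np.unique(y_true)) < 2:
                y_true = rng.integers(0, k, size=n)
            y_pred = rng.integers(0, k, size=n)
            labels = sorted(set(y_true) | set(y_pred))
            if k == 2:
                scores = rng.normal(size=n)
                m = compute_metrics(y_true, y_pred, scores=scores)
                assert m["roc_auc"] == pytest.approx(
                    oracle.mann_whitney_auc(y_true, scores), abs=1e-12)
            else:
                raw = rng.uniform(size=(n, k))
                scores = raw / raw.sum(axis=1, keepdims=True)
                m = compute_metrics(y_true, y_pred, scores=scores)
            assert m["accuracy"] == pytest.approx(
                oracle.brute_accuracy(y_true, y_pred), abs=1e-12)
            assert m["precision"] == pytest.approx(
                oracle.brute_weighted_precision(y_true, y_pred, labels), abs=1e-12)
            assert m["f_measure"] == pytest.approx(
                oracle.brute_weighted_f1(y_true, y_pred, labels), abs=1e-12)
            assert m["mcc"] == pytest.approx(
                oracle.brute_mcc(y_true, y_pred, labels), abs=1e-12)


class TestGaussianNoise:
    def test_injected_sd_matches_definition(self):
        # level 100 -> noise sd equals the reference sd (within 2% at 1e5 draws)
        features = np.zeros((100000, 2), dtype=np.float32)
        ref_sd = np.array([1.5, 0.5])
        noisy = add_gaussian_noise(features, 100, ref_sd, seed=0)
        np.testing.assert_allclose(noisy.std(axis=0), ref_sd, rtol=0.02)
        assert abs(noisy.mean()) < 0.02  # zero-mean draws

    def test_small_level_converges_to_input(self):
        rng = np.random.default_rng(1)
        features = rng.normal(size=(50, 4)).astype(np.float32)
        noisy = add_gaussian_noise(features, 1e-4, np.ones(4), seed=2)
        np.testing.assert_allclose(noisy, features, atol=1e-4)

    def test_constant_feature_unchanged(self):
        features = np.full((10, 1), 3.0, dtype=np.float32)
        noisy = add_gaussian_noise(features, 500, np.zeros(1), seed=3)
        np.testing.assert_array_equal(noisy, features)

    def test_nonpositive_level_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            add_gaussian_noise(np.zeros((2, 2)), 0, np.ones(2), seed=0)

    def test_deterministic_under_seed(self):
        f = np.zeros((5, 3), dtype=np.float32)
        a = add_gaussian_noise(f, 50, np.ones(3), seed=9)
        b = add_gaussian_noise(f, 50, np.ones(3), seed=9)
        np.testing.assert_array_equal(a, b)


class TestRobustnessCurve:
    @pytest.fixture
    def model(self):
        return GeneClassifierCNN(ModelConfig(**SMALL, head_arity=2, seed=0))

    def test_includes_clean_baseline(self, model):
        rng = np.random.default_rng(0)
        feats = rng.normal(size=(20, 9)).astype(np.float32)
        labels = rng.integers(0, 2, size=20)
        curve = robustness_curve(model, feats, labels, np.ones(9),
                                 levels=(1, 10, 50, 100, 500, 1000, 1500),
                                 seed=1)
        assert len(curve) == 8
        assert 0.0 in curve

    def test_deterministic_curve(self, model):
        rng = np.random.default_rng(2)
        feats = rng.normal(size=(15, 9)).astype(np.float32)
        labels = rng.integers(0, 2, size=15)
        a = robustness_curve(model, feats, labels, np.ones(9), seed=5)
        b = robustness_curve(model, feats, labels, np.ones(9), seed=5)
        assert json.dumps(a, sort_keys=True) == json.dumps(b, sort_keys=True)


class TestBaselines:
    @pytest.fixture
    def separable_data(self):
        rng = np.random.default_rng(3)
        n = 90
        labels = np.repeat([0, 1, 2], n // 3)
        feats = rng.normal(size=(n, 8)).astype(np.float32)
        feats[labels == 0, :4] -= 3
        feats[labels == 1, :4] += 3
        return feats, labels

    def test_five_reports_with_shared_schema(self, separable_data):
        feats, labels = separable_data
        test_mask = labels != 2
        reports = run_baselines(feats, labels, feats[test_mask],
                                labels[test_mask], seed=0)
        assert len(reports) == 5
        for rep in reports.values():
            assert set(rep.folds[0]) == {"accuracy", "recall", "precision",
                                         "f_measure", "mcc", "roc_auc"}

    def test_separable_data_high_accuracy(self, separable_data):
        feats, labels = separable_data
        test_mask = labels != 2
        reports = run_baselines(feats, labels, feats[test_mask],
                                labels[test_mask], seed=0)
        for name, rep in reports.items():
            assert rep.folds[0]["accuracy"] > 90, name

    def test_unknown_baseline_rejected(self, separable_data):
        feats, labels = separable_data
        with pytest.raises(ValueError, match="unknown baseline"):
            run_baselines(feats, labels, feats, labels,
                          baseline_ids=("naive-bayes",), seed=0)


class TestReportsOnDisk:
    def test_metrics_report_round_trip(self, tmp_path):
        rep = MetricsReport(model="m", dataset="d", n_classes=2,
                            folds=[{"accuracy": 97.5, "recall": 97.5,
                                    "precision": 98.0, "f_measure": 0.97,
                                    "mcc": 0.95, "roc_auc": 0.99}], seed=3)
        write_metrics_report(rep, tmp_path / "r.json")
        back = read_metrics_report(tmp_path / "r.json")
        assert back[0]["folds"] == rep.folds
        assert back[0]["mean"]["mcc"] == pytest.approx(0.95)

    def test_empty_report_list_valid(self, tmp_path):
        write_metrics_report([], tmp_path / "r.json")
        assert read_metrics_report(tmp_path / "r.json") == []

    def test_roc_points_span_unit_square(self, tmp_path):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, size=50)
        scores = y + rng.normal(scale=0.5, size=50)
        write_roc_points({"cnn": (y, scores)}, tmp_path / "roc.tsv")
        lines = (tmp_path / "roc.tsv").read_text().strip().splitlines()
        first = lines[1].split("\t")
        last = lines[-1].split("\t")
        assert (float(first[2]), float(first[3])) == (0.0, 0.0)
        assert (float(last[2]), float(last[3])) == (1.0, 1.0)
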