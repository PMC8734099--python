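"""Model evaluation: the six-metric report, noise robustness, baselines.

Every evaluation emits the same six quantities — accuracy, recall and
precision as percentages, F-measure, Matthews correlation coefficient
(MCC), and ROC-AUC — with support-weighted averaging across classes.
Support-weighted recall is mathematically identical to accuracy (both
equal the trace of the confusion matrix over its total), and that
identity is asserted on every report.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn import metrics as skm

logger = logging.getLogger(__name__)

METRIC_FIELDS = ("accuracy", "recall", "precision", "f_measure", "mcc", "roc_auc")
DEFAULT_NOISE_LEVELS = (1, 10, 50, 100, 500, 1000, 1500)
BASELINE_IDS = (
    "decision-tree",
    "k-nearest-neighbors",
    "random-forest",
    "support-vector",
    "gradient-boosted-trees",
)


def compute_metrics(y_true, y_pred, scores=None) -> dict:
    """The six-metric record for one set of predictions.

    ``scores``: for binary problems a 1-D array of scores for class 1; for
    multiclass an (n, k) array of per-class probabilities. With a
    single-class truth vector ROC is undefined and reported as NaN with a
    warning instead of raising.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("true and predicted label vectors differ in length")
    if y_true.size == 0:
        raise ValueError("empty label vectors")
    labels = np.union1d(np.unique(y_true), np.unique(y_pred))
    accuracy = float(np.mean(y_true == y_pred)) * 100.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-support classes
        recall = skm.recall_score(y_true, y_pred, labels=labels,
                                  average="weighted", zero_division=0) * 100.0
        precision = skm.precision_score(y_true, y_pred, labels=labels,
                                        average="weighted", zero_division=0) * 100.0
        f_measure = skm.f1_score(y_true, y_pred, labels=labels,
                                 average="weighted", zero_division=0)
        mcc = skm.matthews_corrcoef(y_true, y_pred)
    assert abs(accuracy - recall) < 1e-9, "accuracy must equal weighted recall"

    roc_auc = float("nan")
    true_classes = np.unique(y_true)
    if scores is None or len(true_classes) < 2:
        if len(true_classes) < 2:
            logger.warning("single-class truth: ROC-AUC undefined, reported as NaN")
    else:
        scores = np.asarray(scores, dtype=np.float64)
        if scores.ndim == 1 or scores.shape[1] == 1:
            roc_auc = float(skm.roc_auc_score(y_true, scores.reshape(-1)))
        elif len(true_classes) == 2 and scores.shape[1] == 2:
            roc_auc = float(skm.roc_auc_score(y_true, scores[:, 1]))
        else:
            roc_auc = float(skm.roc_auc_score(
                y_true, scores, multi_class="ovr", average="weighted",
                labels=np.arange(scores.shape[1]),
            ))
    return {
        "accuracy": accuracy,
        "recall": recall,
        "precision": precision,
        "f_measure": float(f_measure),
        "mcc": float(mcc),
        "roc_auc": roc_auc,
    }


@dataclass
class MetricsReport:
    """Per-fold and aggregated six-metric evaluation record."""

    model: str
    dataset: str
    n_classes: int
    folds: list[dict] = field(default_factory=list)
    averaging: str = "weighted"
    seed: int | None = None
    extra: dict = field(default_factory=dict)

    @property
    def mean(self) -> dict:
        if not self.folds:
            return {k: float("nan") for k in METRIC_FIELDS}
        out = {}
        for k in METRIC_FIELDS:
            vals = np.array([f[k] for f in self.folds], dtype=np.float64)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                out[k] = float(np.nanmean(vals))
        return out

    def to_dict(self) -> dict:
        d = {
            "model": self.model,
            "dataset": self.dataset,
            "n_classes": self.n_classes,
            "averaging": self.averaging,
            "folds": self.folds,
            "mean": self.mean,
            "seed": self.seed,
        }
        if self.extra:
            d["extra"] = self.extra
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2,
                          allow_nan=True)


def write_metrics_report(reports, path) -> None:
    """Write one or more reports as a versioned JSON document."""
    if isinstance(reports, MetricsReport):
        reports = [reports]
    doc = {"schema_version": 1,
           "reports": [r.to_dict() for r in reports]}
    with open(path, "w") as fh:
        json.dump(doc, fh, sort_keys=True, indent=2)
        fh.write("\n")


def read_metrics_report(path) -> list[dict]:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("schema_version") != 1:
        raise ValueError(f"{path}: unsupported metrics schema")
    return doc["reports"]


def write_roc_points(named_results: dict, path) -> None:
    """Write (model, threshold, fpr, tpr) rows per model for external plotting.

    ``named_results`` maps a model name to (y_true, scores) with binary
    truth and class-1 scores. Curves run from (0, 0) to (1, 1).
    """
    with open(path, "w") as fh:
        fh.write("model\tthreshold\tfpr\ttpr\n")
        for name, (y_true, scores) in named_results.items():
            fpr, tpr, thr = skm.roc_curve(y_true, scores)
            # roc_curve's first threshold is inf; pin the endpoints
            for t, f, tp in zip(thr, fpr, tpr):
                tstr = "inf" if np.isinf(t) else f"{t:.10g}"
                fh.write(f"{name}\t{tstr}\t{f:.10g}\t{tp:.10g}\n")
            if not (fpr[0] == 0 and tpr[0] == 0 and fpr[-1] == 1 and tpr[-1] == 1):
                raise AssertionError("ROC curve endpoints must be (0,0) and (1,1)")


# --------------------------------------------------------------------------
# Gaussian-noise robustness

def add_gaussian_noise(features: np.ndarray, level: float,
                       reference_sd: np.ndarray, seed: int) -> np.ndarray:
    """Inject zero-mean Gaussian noise at ``level`` percent of each
    feature's reference standard deviation.

    ``reference_sd`` must come from training data only; constant features
    (sd 0) pass through unchanged. Deterministic under ``seed``.
    """
    if level <= 0:
        raise ValueError("noise level must be positive (percent of reference sd)")
    features = np.asarray(features, dtype=np.float32)
    reference_sd = np.asarray(reference_sd, dtype=np.float64).reshape(1, -1)
    if reference_sd.shape[1] != features.shape[1]:
        raise ValueError("reference sd length must match the feature count")
    rng = np.random.default_rng(int(seed))
    noise = rng.standard_normal(features.shape) * (level / 100.0) * reference_sd
    return (features + noise).astype(np.float32)


def robustness_curve(model, features, labels, reference_sd,
                     levels=DEFAULT_NOISE_LEVELS, seed: int = 0,
                     dataset: str = "dataset") -> dict[float, dict]:
    """Evaluate a frozen model on noise-corrupted copies of the test set.

    Returns {level: metric dict}, always including the clean baseline at
    level 0. Each level draws from an independent stream derived from
    ``seed`` and the level's position.
    """
    labels = np.asarray(labels)
    out: dict[float, dict] = {}
    binary = model.config.head_arity == 2
    for i, level in enumerate([0] + list(levels)):
        x = features if level == 0 else add_gaussian_noise(
            features, level, reference_sd, seed=np.random.SeedSequence(
                [int(seed), i]).generate_state(1)[0] % (2**31))
        pred = model.predict_classes(x)
        sc = model.predict_scores(x)
        scores = _binary_scores(sc) if binary else _softmax64(sc)
        out[float(level)] = compute_metrics(labels, pred, scores)
    return out


def _softmax64(logits):
    z = np.asarray(logits, dtype=np.float64)
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _binary_scores(logits) -> np.ndarray:
    """Class-1 score from a two-column logit array."""
    z = np.asarray(logits, dtype=np.float64)
    return (z[:, 1] - z[:, 0])


# --------------------------------------------------------------------------
# Classical baselines

def _make_baseline(baseline_id: str, seed: int):
    if baseline_id == "decision-tree":
        from sklearn.tree import DecisionTreeClassifier
        return DecisionTreeClassifier(random_state=seed)
    if baseline_id == "k-nearest-neighbors":
        from sklearn.neighbors import KNeighborsClassifier
        return KNeighborsClassifier()
    if baseline_id == "random-forest":
        from sklearn.ensemble import RandomForestClassifier
        return RandomForestClassifier(random_state=seed)
    if baseline_id == "support-vector":
        from sklearn.svm import SVC
        return SVC(probability=True, random_state=seed)
    if baseline_id == "gradient-boosted-trees":
        from xgboost import XGBClassifier
        return XGBClassifier(random_state=seed, n_jobs=1, eval_metric="mlogloss")
    raise ValueError(f"unknown baseline id {baseline_id!r}")


def run_baselines(train_features, train_labels, test_features, test_labels,
                  baseline_ids=BASELINE_IDS, seed: int = 0,
                  dataset: str = "dataset") -> dict[str, MetricsReport]:
    """Fit each classical classifier on the CNN's training data and score
    the same test indices.

    The classical methods have no head-swap analogue, so each is fit once
    on the union of the first-level training set and the fine-tune set,
    restricted to the evaluation's label space (up/down genes only — the
    closest fair analogue of the CNN's two-level scheme, whose final model
    is a two-class classifier), and evaluated on the binary test set.
    Binary ROC scores renormalize the up/down class probabilities.
    """
    train_features = np.asarray(train_features)
    test_features = np.asarray(test_features)
    train_labels = np.asarray(train_labels)
    test_labels = np.asarray(test_labels)
    eval_space = np.unique(test_labels)
    keep = np.isin(train_labels, eval_space)
    train_features = train_features[keep]
    train_labels = train_labels[keep]
    out: dict[str, MetricsReport] = {}
    for bid in baseline_ids:
        clf = _make_baseline(bid, seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            clf.fit(train_features, train_labels)
        pred = clf.predict(test_features)
        proba = clf.predict_proba(test_features)
        cls = list(clf.classes_)
        p0 = proba[:, cls.index(0)] if 0 in cls else np.zeros(len(test_labels))
        p1 = proba[:, cls.index(1)] if 1 in cls else np.zeros(len(test_labels))
        denom = p0 + p1
        denom[denom == 0] = 1.0
        scores = p1 / denom
        fold = compute_metrics(test_labels, pred, scores)
        report = MetricsReport(model=bid, dataset=dataset, n_classes=2,
                               folds=[fold], seed=seed)
        out[bid] = report
    return out
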