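"""Two-level training and cross-dataset transfer.

Experiment 1 (general learning): five-fold cross-validated 3-class
training on the non-bio training genes T1 with multiclass cross-entropy
(50 epochs, batch 256), selection of the best fold by validation MCC,
replacement of the output head by a 2-unit layer, 2-class fine-tuning on
the bio fine-tune genes F1 with sigmoid cross-entropy on raw scores
(31 epochs, batch 64), and final evaluation on the bio-test genes T3.

Experiment 2 (transfer learning): the same two-level scheme applied
sequentially across several source datasets — 3-class training on each
source's T1 one after another carrying weights forward, one head swap,
sequential fine-tuning on each source's F1 — followed by frozen
prediction on unseen datasets composed entirely of validated up/down
genes. No gradients flow during the test phase; the adaptive pooling
lets one set of weights score datasets of any sample count.

All entry points are deterministic functions of (data, config, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .evaluation import MetricsReport, _binary_scores, _softmax64, compute_metrics
from .io import state_hash
from .labeling import LABEL_NEUTRAL, DataSplit, LabeledGeneSet, make_cv_folds
from .model import GeneClassifierCNN, ModelConfig

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Optimization hyperparameters for both training levels.

    Defaults: 50 epochs at batch 256 with multiclass cross-entropy for the
    first level, 31 epochs at batch 64 with sigmoid cross-entropy for
    fine-tuning, Adam at lr 1e-4, betas (0.9, 0.999), eps 1e-8, no weight
    decay, five folds.
    """

    level1_epochs: int = 50
    level1_batch: int = 256
    finetune_epochs: int = 31
    finetune_batch: int = 64
    lr: float = 1e-4
    betas: tuple[float, float] = (0.9, 0.999)
    eps: float = 1e-8
    weight_decay: float = 0.0
    folds: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.level1_epochs < 0 or self.finetune_epochs < 0:
            raise ValueError("epoch counts must be non-negative")
        if self.level1_batch < 1 or self.finetune_batch < 1:
            raise ValueError("batch sizes must be positive")
        if self.lr <= 0 or self.eps <= 0:
            raise ValueError("lr and eps must be positive")
        if self.folds < 2:
            raise ValueError("folds must be at least 2")

    def to_dict(self) -> dict:
        return {
            "level1_epochs": self.level1_epochs,
            "level1_batch": self.level1_batch,
            "finetune_epochs": self.finetune_epochs,
            "finetune_batch": self.finetune_batch,
            "lr": self.lr, "betas": list(self.betas), "eps": self.eps,
            "weight_decay": self.weight_decay, "folds": self.folds,
            "seed": self.seed,
        }


@dataclass
class FoldResult:
    fold_index: int
    report: dict  # validation metrics
    model: GeneClassifierCNN
    loss_trace: list[float]


@dataclass
class GeneralLearningResult:
    fold_results: list[FoldResult]
    best_fold: int
    model: GeneClassifierCNN
    t3_report: MetricsReport
    finetune_trace: list[float] = field(default_factory=list)


def _derive_seed(*parts: int) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2**31))


def _epoch_batches(n: int, batch: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for i in range(0, n, batch):
        yield order[i:i + batch]


def train_level1(model: GeneClassifierCNN, features: np.ndarray,
                 labels: np.ndarray, config: TrainConfig,
                 seed: int | None = None) -> list[float]:
    """First-level 3-class training with multiclass cross-entropy.

    Batches are reshuffled every epoch; returns per-epoch mean losses.
    With ``level1_epochs == 0`` the model is returned untouched.
    """
    features = np.asarray(features, dtype=np.float32)
    labels = np.asarray(labels)
    if model.config.head_arity != 3:
        raise ValueError("first-level training expects a 3-class head")
    present = set(np.unique(labels).tolist())
    missing = {0, 1, 2} - present
    if missing:
        logger.warning("label classes %s absent from the training set; "
                       "training proceeds", sorted(missing))
    rng = np.random.default_rng(_derive_seed(config.seed if seed is None else seed, 1))
    opt = nn.Adam(model.parameters(), lr=config.lr, betas=config.betas,
                  eps=config.eps, weight_decay=config.weight_decay)
    trace = []
    for _epoch in range(config.level1_epochs):
        losses, counts = [], []
        for idx in _epoch_batches(len(labels), config.level1_batch, rng):
            logits = model.forward_logits(features[idx], train=True)
            loss, dlogits = nn.softmax_cross_entropy(logits, labels[idx])
            model.backward(dlogits)
            opt.step()
            opt.zero_grad()
            losses.append(loss)
            counts.append(len(idx))
        trace.append(float(np.average(losses, weights=counts)))
        logger.debug("level1 epoch %d loss %.5f", _epoch, trace[-1])
    return trace


def cross_validate_level1(model_factory, features: np.ndarray,
                          labels: np.ndarray, folds: list[np.ndarray],
                          config: TrainConfig,
                          dataset: str = "dataset") -> tuple[list[FoldResult], int]:
    """Train one model per CV round; select the best by validation MCC.

    ``folds`` are validation index sets from :func:`make_cv_folds` (indices
    into the full gene set; features/labels are indexed directly). Ties in
    MCC resolve to the lower fold index.
    """
    results: list[FoldResult] = []
    for i, val_idx in enumerate(folds):
        train_idx = np.sort(np.concatenate([f for j, f in enumerate(folds) if j != i]))
        model = model_factory(i)
        trace = train_level1(model, features[train_idx], labels[train_idx],
                             config, seed=_derive_seed(config.seed, 100 + i))
        pred = model.predict_classes(features[val_idx])
        scores = _softmax64(model.predict_scores(features[val_idx]))
        report = compute_metrics(labels[val_idx], pred, scores)
        results.append(FoldResult(fold_index=i, report=report, model=model,
                                  loss_trace=trace))
    mccs = np.array([r.report["mcc"] for r in results])
    best = int(np.argmax(mccs))  # argmax takes the first maximum on ties
    return results, best


def finetune(model: GeneClassifierCNN, features: np.ndarray,
             labels: np.ndarray, config: TrainConfig,
             seed: int | None = None) -> list[float]:
    """Second-level 2-class training with sigmoid cross-entropy on logits.

    Expects the head already swapped to arity 2 and labels in {0, 1},
    one-hot encoded as two real targets. The whole backbone is updated —
    no layers are frozen.
    """
    features = np.asarray(features, dtype=np.float32)
    labels = np.asarray(labels)
    if model.config.head_arity != 2:
        raise ValueError("fine-tuning expects the 2-class head (swap_head first)")
    if np.any(labels == LABEL_NEUTRAL):
        raise ValueError("fine-tune data must contain only labels {0, 1}")
    targets = np.zeros((len(labels), 2), dtype=np.float32)
    targets[np.arange(len(labels)), labels] = 1.0
    rng = np.random.default_rng(_derive_seed(config.seed if seed is None else seed, 2))
    opt = nn.Adam(model.parameters(), lr=config.lr, betas=config.betas,
                  eps=config.eps, weight_decay=config.weight_decay)
    trace = []
    for _epoch in range(config.finetune_epochs):
        losses, counts = [], []
        for idx in _epoch_batches(len(labels), config.finetune_batch, rng):
            logits = model.forward_logits(features[idx], train=True)
            loss, dlogits = nn.sigmoid_cross_entropy(logits, targets[idx])
            model.backward(dlogits)
            opt.step()
            opt.zero_grad()
            losses.append(loss)
            counts.append(len(idx))
        trace.append(float(np.average(losses, weights=counts)))
        logger.debug("finetune epoch %d loss %.5f", _epoch, trace[-1])
    return trace


def _evaluate_binary(model: GeneClassifierCNN, features, labels) -> dict:
    pred = model.predict_classes(features)
    scores = _binary_scores(model.predict_scores(features))
    return compute_metrics(labels, pred, scores)


def run_general_learning(labels: LabeledGeneSet, split: DataSplit,
                         model_config: ModelConfig | None = None,
                         config: TrainConfig | None = None) -> GeneralLearningResult:
    """The full first experiment on one dataset.

    Cross-validated 3-class training on T1, best fold by validation MCC,
    head swap to 2 classes, fine-tuning on F1, binary evaluation on T3.
    The returned report carries the T3 metrics as its single fold entry and
    the per-fold validation metrics under ``extra``.
    """
    config = config or TrainConfig()
    model_config = model_config or ModelConfig(seed=_derive_seed(config.seed, 10))
    folds = make_cv_folds(labels.labels, split.T1, k=config.folds,
                          seed=_derive_seed(config.seed, 20))

    def factory(fold_index: int) -> GeneClassifierCNN:
        rng = np.random.default_rng(_derive_seed(config.seed, 30 + fold_index))
        return GeneClassifierCNN(model_config, rng=rng)

    fold_results, best = cross_validate_level1(
        factory, labels.features, labels.labels, folds, config,
        dataset=labels.name)
    model = fold_results[best].model.swap_head(
        2, rng=np.random.default_rng(_derive_seed(config.seed, 40)))
    ft_trace = finetune(model, labels.features[split.F1],
                        labels.labels[split.F1], config,
                        seed=_derive_seed(config.seed, 50))
    t3_metrics = _evaluate_binary(model, labels.features[split.T3],
                                  labels.labels[split.T3])
    report = MetricsReport(
        model="gene-direction-cnn", dataset=labels.name, n_classes=2,
        folds=[t3_metrics], seed=config.seed,
        extra={
            "cv_validation": [r.report for r in fold_results],
            "best_fold": best,
            "split_seed": int(split.seed),
        },
    )
    return GeneralLearningResult(fold_results=fold_results, best_fold=best,
                                 model=model, t3_report=report,
                                 finetune_trace=ft_trace)


def run_transfer_learning(
    train_sets: list[tuple[LabeledGeneSet, DataSplit]],
    test_sets: list[LabeledGeneSet],
    model_config: ModelConfig | None = None,
    config: TrainConfig | None = None,
) -> tuple[dict[str, MetricsReport], GeneClassifierCNN]:
    """The second experiment: sequential multi-dataset transfer.

    Phase A trains the 3-class model on each source dataset's T1 in order,
    carrying weights forward; phase B swaps the head once and fine-tunes
    sequentially on each source's F1; phase C evaluates the frozen model
    on every test dataset (which must contain only up/down labels). The
    returned reports record the dataset order and the frozen-weights hash.
    """
    if not train_sets:
        raise ValueError("at least one training dataset is required")
    for ts in test_sets:
        if np.any(ts.labels == LABEL_NEUTRAL):
            raise ValueError(
                f"test dataset {ts.name!r} contains neutral labels; transfer "
                "testing expects 100% validated up/down genes"
            )
    config = config or TrainConfig()
    model_config = model_config or ModelConfig(seed=_derive_seed(config.seed, 10))
    model = GeneClassifierCNN(
        model_config, rng=np.random.default_rng(_derive_seed(config.seed, 60)))

    for i, (labels, split) in enumerate(train_sets):  # phase A
        train_level1(model, labels.features[split.T1], labels.labels[split.T1],
                     config, seed=_derive_seed(config.seed, 200 + i))

    model = model.swap_head(
        2, rng=np.random.default_rng(_derive_seed(config.seed, 70)))
    for i, (labels, split) in enumerate(train_sets):  # phase B
        finetune(model, labels.features[split.F1], labels.labels[split.F1],
                 config, seed=_derive_seed(config.seed, 300 + i))

    frozen_hash = state_hash(model.state_arrays())
    order = [labels.name for labels, _ in train_sets]
    reports: dict[str, MetricsReport] = {}
    for ts in test_sets:  # phase C — no gradient updates
        fold = _evaluate_binary(model, ts.features, ts.labels)
        reports[ts.name] = MetricsReport(
            model="gene-direction-cnn-transfer", dataset=ts.name, n_classes=2,
            folds=[fold], seed=config.seed,
            extra={"train_order": order, "frozen_weights_sha256": frozen_hash},
        )
    assert state_hash(model.state_arrays()) == frozen_hash
    return reports, model
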