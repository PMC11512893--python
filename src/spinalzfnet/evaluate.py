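"""Training control and the evaluation metric suite.

Training follows the stated protocol: softmax cross-entropy, batch size 32,
base learning rate 0.001, plateau halving (monitor validation accuracy,
patience 5, minimum change 1e-4, factor 0.5), best-checkpoint restore and
early stopping after 50 non-improving epochs.

Metrics reduce the 4-class confusion matrix one-vs-rest per class:
accuracy (TP+TN)/(TP+TN+FP+FN), sensitivity TP/(TP+FN), precision
TP/(TP+FP), specificity TN/(TN+FP) and F1 = 2·P·S/(P+S), reported as
percentages with unweighted macro averages.  Zero-denominator metrics are
reported as 0 with an explicit flag so fold aggregation stays total.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import auc as sk_auc
from sklearn.metrics import roc_curve as sk_roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import nn
from .autodiff import Tensor
from .errors import ConfigurationError
from .model import ClassificationDataset, SpinalZFNet
from .phantom import CLASSES

N_CLASSES = len(CLASSES)


@dataclass(frozen=True)
class TrainConfig:
    optimizer: str = "Adam"           # Adam | SGD | RMSProp
    batch_size: int = 32
    max_epochs: int = 100
    lr: float = 0.001
    plateau_patience: int = 5
    plateau_min_delta: float = 1e-4
    plateau_factor: float = 0.5
    early_stop_patience: int = 50
    weight_decay: float = 1e-3
    image_branch_weight_decay: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.lr <= 0:
            raise ConfigurationError(f"lr must be > 0, got {self.lr}")
        if self.plateau_patience < 1:
            raise ConfigurationError(
                f"plateau_patience must be >= 1, got {self.plateau_patience}")
        if self.batch_size < 1:
            raise ConfigurationError(f"batch_size must be >= 1, got {self.batch_size}")


class TrainingController:
    """Plateau LR halving + early stopping + best-checkpoint bookkeeping.

    Driven once per epoch with the monitored validation accuracy; usable with
    any model exposing ``state_dict``/``load_state_dict`` (including scripted
    stubs in tests).
    """

    def __init__(self, config: TrainConfig):
        self.config = config
        self.lr = config.lr
        self.best_metric = -np.inf
        self.best_epoch = 0
        self.best_state: dict | None = None
        self._since_improvement = 0   # epochs since improvement, for the plateau
        self.lr_halving_epochs: list[int] = []
        self.stopped_epoch: int | None = None

    def update(self, epoch: int, metric: float, model=None) -> bool:
        """Record one epoch; returns True if training should stop."""
        cfg = self.config
        if metric > self.best_metric + cfg.plateau_min_delta:
            self.best_metric = metric
            self.best_epoch = epoch
            self._since_improvement = 0
            if model is not None:
                self.best_state = copy.deepcopy(model.state_dict())
        else:
            self._since_improvement += 1
            if self._since_improvement >= cfg.plateau_patience:
                self.lr *= cfg.plateau_factor
                self.lr_halving_epochs.append(epoch)
                self._since_improvement = 0
        if epoch - self.best_epoch >= cfg.early_stop_patience:
            self.stopped_epoch = epoch
            return True
        return False

    def restore_best(self, model) -> None:
        if self.best_state is not None:
            model.load_state_dict(self.best_state)


def train(model: SpinalZFNet, dataset: ClassificationDataset,
          config: TrainConfig | None = None, val_frac: float = 0.2,
          val_set: ClassificationDataset | None = None,
          ) -> tuple[SpinalZFNet, dict]:
    """Train the classifier with plateau/early-stop/checkpoint control.

    The dataset is canonicalised by sample id (so input order is irrelevant).
    If ``val_set`` is given it monitors training directly (the caller is
    expected to have kept it un-augmented); otherwise a stratified
    ``val_frac`` split is carved from ``dataset``.  Returns the model with
    the best-validation-accuracy weights restored, plus the history.
    """
    config = config or TrainConfig()
    if len(dataset) < 2:
        raise ValueError("training requires at least 2 samples")
    order = np.argsort(dataset.ids, kind="stable")
    dataset = dataset.subset(order)
    if val_set is None:
        idx_train, idx_val = train_test_split(
            np.arange(len(dataset)), test_size=val_frac, random_state=config.seed,
            stratify=dataset.labels)
        train_set = dataset.subset(np.sort(idx_train))
        val_set = dataset.subset(np.sort(idx_val))
    else:
        train_set = dataset
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValueError("empty train or validation split")

    model.fit_scaler(train_set.features)
    x_img = train_set.images
    x_feat = model.scale(train_set.features)
    y = train_set.labels
    controller = TrainingController(config)
    # the raw-image spinal branch and the full-feature map have far more
    # capacity than the phantom task needs; they get heavier shrinkage than
    # the compact statistical/shape paths so that training favours the
    # generalising features over memorisation
    heavy = [p for name, p in model.named_parameters()
             if name.startswith("spinal.") or "full_map" in name]
    heavy_ids = {id(p) for p in heavy}
    light = [p for p in model.parameters() if id(p) not in heavy_ids]
    opt_heavy = nn.make_optimizer(config.optimizer, heavy, config.lr,
                                  weight_decay=config.image_branch_weight_decay)
    optimizer = nn.make_optimizer(config.optimizer, light, config.lr,
                                  weight_decay=config.weight_decay)
    rng = np.random.default_rng(config.seed)
    history = {"train_loss": [], "train_acc": [], "val_loss": [], "val_acc": [],
               "lr": []}
    n = len(train_set)
    for epoch in range(1, config.max_epochs + 1):
        optimizer.lr = controller.lr
        opt_heavy.lr = controller.lr
        model.train(True)
        perm = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, config.batch_size):
            batch = perm[start:start + config.batch_size]
            logits = model.forward(Tensor(x_img[batch]), Tensor(x_feat[batch]))
            loss = nn.cross_entropy(logits, y[batch])
            model.zero_grad()
            loss.backward()
            optimizer.step()
            opt_heavy.step()
            losses.append(float(loss.data))
            correct += int((logits.data.argmax(axis=1) == y[batch]).sum())
        val_loss, val_acc = _evaluate_split(model, val_set)
        history["train_loss"].append(float(np.mean(losses)))
        history["train_acc"].append(correct / n)
        history["val_loss"].append(val_loss)
        history["val_acc"].append(val_acc)
        history["lr"].append(controller.lr)
        if controller.update(epoch, val_acc, model):
            break
    controller.restore_best(model)
    history["best_epoch"] = controller.best_epoch
    history["lr_halving_epochs"] = controller.lr_halving_epochs
    return model, history


def _evaluate_split(model: SpinalZFNet, subset: ClassificationDataset,
                    ) -> tuple[float, float]:
    model.train(False)
    logits = model.forward(Tensor(subset.images),
                           Tensor(model.scale(subset.features)))
    loss = float(nn.cross_entropy(logits, subset.labels).data)
    acc = float((logits.data.argmax(axis=1) == subset.labels).mean())
    return loss, acc


# ---------------------------------------------------------------------------
# confusion counts and metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionCounts:
    matrix: np.ndarray  # rows = true class, columns = predicted class

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.int64)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("confusion matrix must be square")

    @classmethod
    def from_predictions(cls, y_true, y_pred, n_classes: int = N_CLASSES):
        matrix = np.zeros((n_classes, n_classes), dtype=np.int64)
        for t, p in zip(np.asarray(y_true), np.asarray(y_pred)):
            matrix[t, p] += 1
        return cls(matrix)

    @property
    def n_classes(self) -> int:
        return self.matrix.shape[0]

    def one_vs_rest(self, cls_idx: int) -> tuple[int, int, int, int]:
        """(TP, TN, FP, FN) treating ``cls_idx`` as positive."""
        total = self.matrix.sum()
        tp = self.matrix[cls_idx, cls_idx]
        fn = self.matrix[cls_idx].sum() - tp
        fp = self.matrix[:, cls_idx].sum() - tp
        tn = total - tp - fn - fp
        return int(tp), int(tn), int(fp), int(fn)


@dataclass
class EvalReport:
    """Per-class and macro metrics (percent) plus provenance."""

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    per_class: dict[str, dict[str, float]]
    confusion: np.ndarray
    flags: list[str] = field(default_factory=list)
    roc: dict | None = None
    provenance: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        out = {
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "precision": self.precision,
            "f1": self.f1, "per_class": self.per_class,
            "confusion": self.confusion.tolist(), "flags": self.flags,
            "provenance": self.provenance,
        }
        if self.roc is not None:
            out["roc_auc"] = {k: v for k, v in self.roc.items() if k.endswith("auc")}
        return out


def _safe_ratio(num: float, den: float, name: str, flags: list[str]) -> float:
    if den == 0:
        flags.append(f"{name}: zero denominator, reported as 0")
        return 0.0
    return num / den


def compute_metrics(counts: ConfusionCounts,
                    class_names: tuple[str, ...] = CLASSES) -> EvalReport:
    """One-vs-rest metrics per class and unweighted macro averages, in %."""
    flags: list[str] = []
    per_class: dict[str, dict[str, float]] = {}
    macro = {"accuracy": [], "sensitivity": [], "specificity": [],
             "precision": [], "f1": []}
    for idx in range(counts.n_classes):
        name = class_names[idx] if idx < len(class_names) else str(idx)
        tp, tn, fp, fn = counts.one_vs_rest(idx)
        accuracy = _safe_ratio(tp + tn, tp + tn + fp + fn, f"{name}.accuracy", flags)
        sensitivity = _safe_ratio(tp, tp + fn, f"{name}.sensitivity", flags)
        precision = _safe_ratio(tp, tp + fp, f"{name}.precision", flags)
        specificity = _safe_ratio(tn, tn + fp, f"{name}.specificity", flags)
        f1 = _safe_ratio(2 * precision * sensitivity, precision + sensitivity,
                         f"{name}.f1", flags)
        values = {"accuracy": accuracy, "sensitivity": sensitivity,
                  "specificity": specificity, "precision": precision, "f1": f1}
        per_class[name] = {k: 100.0 * v for k, v in values.items()}
        for k, v in values.items():
            macro[k].append(v)
    return EvalReport(
        accuracy=100.0 * float(np.mean(macro["accuracy"])),
        sensitivity=100.0 * float(np.mean(macro["sensitivity"])),
        specificity=100.0 * float(np.mean(macro["specificity"])),
        precision=100.0 * float(np.mean(macro["precision"])),
        f1=100.0 * float(np.mean(macro["f1"])),
        per_class=per_class,
        confusion=counts.matrix,
        flags=flags,
    )


def overall_accuracy(counts: ConfusionCounts) -> float:
    """Plain multiclass accuracy (trace over total), in %."""
    return 100.0 * float(np.trace(counts.matrix) / counts.matrix.sum())


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

def roc_curves(y_true: np.ndarray, proba: np.ndarray,
               class_names: tuple[str, ...] = CLASSES) -> dict:
    """One-vs-rest, micro (pooled) and macro (averaged) ROC curves + AUCs.

    Classes absent from ``y_true`` get ``None`` entries (AUC undefined).
    """
    y_true = np.asarray(y_true)
    proba = np.asarray(proba)
    if not np.allclose(proba.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    n_classes = proba.shape[1]
    onehot = np.eye(n_classes)[y_true]
    out: dict = {}
    fpr_grid = np.linspace(0.0, 1.0, 101)
    mean_tpr = np.zeros_like(fpr_grid)
    n_defined = 0
    for idx in range(n_classes):
        name = class_names[idx] if idx < len(class_names) else str(idx)
        if len(np.unique(onehot[:, idx])) < 2:
            out[name] = None
            out[f"{name}_auc"] = None
            continue
        fpr, tpr, _ = sk_roc_curve(onehot[:, idx], proba[:, idx])
        out[name] = (fpr, tpr)
        out[f"{name}_auc"] = float(sk_auc(fpr, tpr))
        mean_tpr += np.interp(fpr_grid, fpr, tpr)
        n_defined += 1
    fpr_micro, tpr_micro, _ = sk_roc_curve(onehot.ravel(), proba.ravel())
    out["micro"] = (fpr_micro, tpr_micro)
    out["micro_auc"] = float(sk_auc(fpr_micro, tpr_micro))
    if n_defined:
        mean_tpr /= n_defined
        out["macro"] = (fpr_grid, mean_tpr)
        out["macro_auc"] = float(sk_auc(fpr_grid, mean_tpr))
    else:
        out["macro"] = None
        out["macro_auc"] = None
    return out


# ---------------------------------------------------------------------------
# K-fold and learning-set protocols
# ---------------------------------------------------------------------------

def _report_from_predictions(y_true, y_pred, proba=None) -> EvalReport:
    counts = ConfusionCounts.from_predictions(y_true, y_pred)
    report = compute_metrics(counts)
    if proba is not None and len(np.unique(y_true)) > 1:
        report.roc = roc_curves(np.asarray(y_true), np.asarray(proba))
    return report


def kfold_evaluate(samples: list, k: int, trainer, seed: int = 0,
                   ) -> tuple[list[EvalReport], EvalReport]:
    """Stratified K-fold evaluation.

    ``trainer(train_samples, test_samples)`` must return ``(y_true, y_pred,
    proba_or_None)`` for the held-out fold; it owns augmentation (training
    folds only) and fitting.  Returns per-fold reports and the aggregate
    (mean of macro metrics, summed confusion).
    """
    labels = np.array([CLASSES.index(s.label) for s in samples])
    if k < 2 or k > len(samples):
        raise ValueError(f"K must satisfy 2 <= K <= n, got {k}")
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    reports = []
    for fold, (train_idx, test_idx) in enumerate(splitter.split(labels, labels)):
        if len(np.unique(labels[train_idx])) < len(np.unique(labels)):
            raise ValueError(f"fold {fold}: a class is absent from the training split")
        y_true, y_pred, proba = trainer([samples[i] for i in train_idx],
                                        [samples[i] for i in test_idx])
        report = _report_from_predictions(y_true, y_pred, proba)
        report.provenance = {"protocol": "kfold", "k": k, "fold": fold, "seed": seed}
        reports.append(report)
    aggregate = EvalReport(
        accuracy=float(np.mean([r.accuracy for r in reports])),
        sensitivity=float(np.mean([r.sensitivity for r in reports])),
        specificity=float(np.mean([r.specificity for r in reports])),
        precision=float(np.mean([r.precision for r in reports])),
        f1=float(np.mean([r.f1 for r in reports])),
        per_class={},
        confusion=np.sum([r.confusion for r in reports], axis=0),
        flags=sorted({f for r in reports for f in r.flags}),
        provenance={"protocol": "kfold", "k": k, "seed": seed, "aggregate": True},
    )
    return reports, aggregate


def learning_set_evaluate(samples: list, train_pct: int, trainer, seed: int = 0,
                          ) -> EvalReport:
    """Single stratified split at ``train_pct`` percent training data."""
    if not (0 < train_pct < 100):
        raise ValueError(f"train_pct must be in (0, 100), got {train_pct}")
    labels = np.array([CLASSES.index(s.label) for s in samples])
    idx_train, idx_test = train_test_split(
        np.arange(len(samples)), train_size=train_pct / 100.0,
        random_state=seed, stratify=labels)
    y_true, y_pred, proba = trainer([samples[i] for i in idx_train],
                                    [samples[i] for i in idx_test])
    report = _report_from_predictions(y_true, y_pred, proba)
    report.provenance = {"protocol": "learning_set", "train_pct": train_pct,
                         "seed": seed}
    return report
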