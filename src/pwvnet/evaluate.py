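"""Training protocol and classification metrics.

The evaluation protocol is a stratified repeated holdout: per class, 67% of
the items train and 33% test, repeated (default five times) with fresh random
selections, and per-repeat metrics averaged arithmetically.

Metrics are one-vs-rest per class, in percent:

    accuracy    = (TP + TN) / (TP + FP + TN + FN) * 100
    sensitivity = TP / (TP + FN) * 100
    specificity = TN / (TN + FP) * 100
    f_score     = 2 TP / (2 TP + FP + FN) * 100

"Global" specificity pools all non-target classes; per-class specificity
against class c' counts the fraction of c' items not predicted as the
target.  The shockable collapse maps {VT, VF} -> positive and
{Normal, Other} -> negative before applying the binary formulas, so
VT/VF confusions do not count as errors there.

Metrics whose denominator is empty are reported as None (undefined), never
coerced to 0 or 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nn import Adam, cross_entropy
from .models import N_CLASSES, TrainedModel
from .preprocess import CLASS_ORDER, SHOCKABLE, RhythmClass

DEFAULT_TRAIN_FRAC = 0.67
DEFAULT_REPEATS = 5
DEFAULT_LR = 1e-3
DEFAULT_BATCH = 32


def repeated_holdout(labels: np.ndarray, train_frac: float = DEFAULT_TRAIN_FRAC,
                     repeats: int = DEFAULT_REPEATS, seed: int = 0,
                     ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified train/test index partitions.

    Per class c with n_c items, ``round(train_frac * n_c)`` go to training;
    partitions are disjoint and exhaustive, and deterministic in ``seed``.
    Every class must be present with at least 3 items.
    """
    labels = np.asarray(labels)
    for cls in CLASS_ORDER:
        n_c = int(np.sum(labels == cls))
        if n_c < 3:
            raise ValueError(f"class {cls.name} has {n_c} items; need >= 3")
    rng = np.random.default_rng(seed)
    splits = []
    for _ in range(repeats):
        train_idx, test_idx = [], []
        for cls in CLASS_ORDER:
            idx = np.flatnonzero(labels == cls)
            perm = rng.permutation(idx)
            n_train = int(round(train_frac * idx.size))
            train_idx.append(perm[:n_train])
            test_idx.append(perm[n_train:])
        splits.append((np.sort(np.concatenate(train_idx)),
                       np.sort(np.concatenate(test_idx))))
    return splits


def train(model: TrainedModel, images: np.ndarray, labels: np.ndarray,
          epochs: int = 100, lr: float = DEFAULT_LR, batch: int = DEFAULT_BATCH,
          seed: int = 0, validation: tuple[np.ndarray, np.ndarray] | None = None,
          ) -> dict[str, list[float]]:
    """Adam / categorical cross-entropy training.

    Returns a history dict with one entry per epoch: ``loss`` and
    ``accuracy`` on the training set (running, over the epoch's batches) and
    ``val_loss`` / ``val_accuracy`` when a validation pair is supplied.
    ``epochs=0`` leaves the model at its initialization.
    """
    images = np.asarray(images, dtype=np.float32)
    labels = np.asarray(labels, dtype=np.int64)
    if images.shape[0] == 0:
        raise ValueError("training set is empty")
    if images.ndim == 3:
        images = images[..., None]
    conv_input = model.spec.layers[0].kind in ("conv", "maxpool")
    x_all = images if conv_input else images.reshape(images.shape[0], -1)
    onehot = np.eye(N_CLASSES, dtype=np.float32)[labels]

    optimizer = Adam(model.net, lr=lr)
    rng = np.random.default_rng(seed)
    history: dict[str, list[float]] = {"loss": [], "accuracy": []}
    if validation is not None:
        history["val_loss"] = []
        history["val_accuracy"] = []

    n = x_all.shape[0]
    for _ in range(epochs):
        order = rng.permutation(n)
        loss_sum, correct = 0.0, 0
        for start in range(0, n, batch):
            sel = order[start:start + batch]
            loss, probs = model.net.train_step(x_all[sel], onehot[sel], optimizer)
            loss_sum += loss * sel.size
            correct += int(np.sum(probs.argmax(axis=1) == labels[sel]))
        history["loss"].append(loss_sum / n)
        history["accuracy"].append(correct / n)
        if validation is not None:
            xv, yv = validation
            pv = model.predict_proba(xv)
            yv = np.asarray(yv, dtype=np.int64)
            history["val_loss"].append(
                cross_entropy(pv, np.eye(N_CLASSES, dtype=np.float32)[yv]))
            history["val_accuracy"].append(float(np.mean(pv.argmax(axis=1) == yv)))
    return history


@dataclass
class ConfusionMatrix:
    """4x4 counts; rows are true classes, columns predictions."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (N_CLASSES, N_CLASSES) or np.any(self.counts < 0):
            raise ValueError("confusion matrix must be 4x4 with counts >= 0")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion(true_labels: np.ndarray, predicted: np.ndarray) -> ConfusionMatrix:
    true_labels = np.asarray(true_labels, dtype=np.int64)
    predicted = np.asarray(predicted, dtype=np.int64)
    if true_labels.shape != predicted.shape:
        raise ValueError("label vectors must have equal length")
    counts = np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64)
    np.add.at(counts, (true_labels, predicted), 1)
    return ConfusionMatrix(counts)


def _pct(num: float, den: float) -> float | None:
    return None if den == 0 else 100.0 * num / den


def binary_metrics(tp: int, fn: int, fp: int, tn: int) -> dict[str, float | None]:
    return {
        "sensitivity": _pct(tp, tp + fn),
        "specificity": _pct(tn, tn + fp),
        "accuracy": _pct(tp + tn, tp + fn + fp + tn),
        "f_score": _pct(2 * tp, 2 * tp + fp + fn),
    }


def class_metrics(cm: ConfusionMatrix, target: RhythmClass) -> dict:
    """One-vs-rest metrics for ``target`` plus per-class specificities."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    c = cm.counts
    t = int(target)
    tp = int(c[t, t])
    fn = int(c[t].sum() - tp)
    fp = int(c[:, t].sum() - tp)
    tn = int(cm.total - tp - fn - fp)
    out = binary_metrics(tp, fn, fp, tn)
    out["spe_global"] = out.pop("specificity")
    out["spe_vs"] = {
        other.name: _pct(c[int(other)].sum() - c[int(other), t], c[int(other)].sum())
        for other in CLASS_ORDER if other != target
    }
    return out


def shockable_metrics(cm: ConfusionMatrix) -> dict[str, float | None]:
    """Binary metrics after collapsing {VT, VF} vs {Normal, Other}."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    pos = [int(c) for c in CLASS_ORDER if c in SHOCKABLE]
    neg = [int(c) for c in CLASS_ORDER if c not in SHOCKABLE]
    c = cm.counts
    tp = int(c[np.ix_(pos, pos)].sum())
    fn = int(c[np.ix_(pos, neg)].sum())
    fp = int(c[np.ix_(neg, pos)].sum())
    tn = int(c[np.ix_(neg, neg)].sum())
    m = binary_metrics(tp, fn, fp, tn)
    return {"sensitivity": m["sensitivity"], "specificity": m["specificity"],
            "accuracy": m["accuracy"]}


@dataclass
class EvalReport:
    """Per-repeat confusion matrices with averaged metrics."""

    confusions: list[ConfusionMatrix]
    histories: list[dict] = field(default_factory=list)

    def per_class(self) -> dict[str, dict]:
        """Mean one-vs-rest metrics per class over repeats (None-aware)."""
        out: dict[str, dict] = {}
        for cls in CLASS_ORDER:
            metrics = [class_metrics(cm, cls) for cm in self.confusions]
            agg: dict = {}
            for key in ("sensitivity", "spe_global", "accuracy", "f_score"):
                vals = [m[key] for m in metrics if m[key] is not None]
                agg[key] = float(np.mean(vals)) if vals else None
            agg["spe_vs"] = {}
            for other in metrics[0]["spe_vs"]:
                vals = [m["spe_vs"][other] for m in metrics
                        if m["spe_vs"][other] is not None]
                agg["spe_vs"][other] = float(np.mean(vals)) if vals else None
            out[cls.name] = agg
        return out

    def shockable(self) -> dict[str, float | None]:
        metrics = [shockable_metrics(cm) for cm in self.confusions]
        out = {}
        for key in ("sensitivity", "specificity", "accuracy"):
            vals = [m[key] for m in metrics if m[key] is not None]
            out[key] = float(np.mean(vals)) if vals else None
        return out

    def pooled(self) -> ConfusionMatrix:
        return ConfusionMatrix(sum(cm.counts for cm in self.confusions))
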