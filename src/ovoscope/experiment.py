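"""Training and evaluation protocol for the candling classifier.

Implements the full experimental loop: stratified 6:2:2 split, light
training-time augmentation (random horizontal flip, centre crop,
per-channel normalisation with constants estimated from the training
split), mini-batch Adam training with cross-entropy (50 epochs, batch 16,
learning rate 0.001 by default), per-epoch validation tracking, stability
statistics of the validation-accuracy sequence (mean, overall variance,
first/last 10-epoch variances — population denominator), and repeated-round
test evaluation with macro precision/recall/F1 and a confusion matrix.

The deterministic evaluation path makes repeated test rounds identical, so
round-to-round variation is produced by bootstrap resampling of the test
set; reports carry ``round_mode="bootstrap"`` to make that explicit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

from .models import ModelSpec, ResNet, build_classifier
from .nn import Adam, Tensor, softmax_cross_entropy

__all__ = [
    "TrainConfig",
    "EpochRecord",
    "StabilityReport",
    "EvalReport",
    "stratified_split",
    "augment",
    "normalization_constants",
    "train_model",
    "stability_metrics",
    "evaluate_model",
    "compare_attention_variants",
]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 50
    batch_size: int = 16
    learning_rate: float = 1e-3
    split_ratios: tuple[float, float, float] = (0.6, 0.2, 0.2)
    seed: int = 0
    hflip: bool = True
    early_stop_accuracy: float | None = None  # stop once val accuracy reaches this

    def __post_init__(self):
        if abs(sum(self.split_ratios) - 1.0) > 1e-9:
            raise ValueError("split ratios must sum to 1")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


@dataclass(frozen=True)
class EpochRecord:
    epoch: int
    train_loss: float
    val_accuracy: float

    def __post_init__(self):
        if not 0.0 <= self.val_accuracy <= 1.0:
            raise ValueError("val_accuracy must lie in [0, 1]")
        if self.train_loss < 0:
            raise ValueError("train_loss must be >= 0")


@dataclass(frozen=True)
class StabilityReport:
    """Statistics of a per-epoch validation-accuracy sequence."""

    mean_accuracy: float
    overall_std: float
    overall_variance: float
    first10_variance: float | None
    last10_variance: float | None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class EvalReport:
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    confusion: np.ndarray  # (K, K) counts; rows = true class
    round_accuracies: tuple[float, ...]
    mean_variance: float   # population variance of the round accuracies
    rounds: int
    round_mode: str        # "bootstrap": rounds resample the test set

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["confusion"] = np.asarray(self.confusion).tolist()
        d["round_accuracies"] = list(self.round_accuracies)
        return d


def stratified_split(labels, ratios=(0.6, 0.2, 0.2), seed: int = 0
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/val/test index sets preserving per-class
    proportions to within one sample. Seeded shuffle per class."""
    labels = np.asarray(labels)
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    rng = np.random.default_rng(seed)
    train, val, test = [], [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size == 0:
            raise ValueError(f"class {cls} has no samples")
        rng.shuffle(idx)
        n = idx.size
        n_train = int(round(ratios[0] * n))
        n_val = int(round(ratios[1] * n))
        n_val = min(n_val, n - n_train)
        train.append(idx[:n_train])
        val.append(idx[n_train : n_train + n_val])
        test.append(idx[n_train + n_val :])
    return (np.sort(np.concatenate(train)),
            np.sort(np.concatenate(val)),
            np.sort(np.concatenate(test)))


def normalization_constants(images: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel mean/std of a (N, 3, H, W) float image stack."""
    mean = images.mean(axis=(0, 2, 3))
    std = images.std(axis=(0, 2, 3))
    return mean, np.maximum(std, 1e-6)


def augment(image: np.ndarray, mean: np.ndarray, std: np.ndarray,
            train: bool, rng: np.random.Generator | None = None,
            hflip: bool = True, crop_size: int | None = None) -> np.ndarray:
    """Augmentation / normalisation of one (3, H, W) image.

    The evaluation path (train=False) is fully deterministic: centre crop
    and normalisation only. The training path adds a random horizontal
    flip.
    """
    out = image
    if crop_size is not None and crop_size < out.shape[1]:
        top = (out.shape[1] - crop_size) // 2
        left = (out.shape[2] - crop_size) // 2
        out = out[:, top : top + crop_size, left : left + crop_size]
    if train and hflip:
        if rng is None:
            raise ValueError("training-time augmentation needs an rng")
        if rng.random() < 0.5:
            out = out[:, :, ::-1]
    return (out - mean[:, None, None]) / std[:, None, None]


def _accuracy(model: ResNet, images: np.ndarray, labels: np.ndarray) -> float:
    return float((model.predict(images) == labels).mean())


def train_model(model: ResNet, train_images: np.ndarray, train_labels: np.ndarray,
                val_images: np.ndarray, val_labels: np.ndarray,
                config: TrainConfig,
                mean: np.ndarray | None = None, std: np.ndarray | None = None,
                ) -> tuple[ResNet, list[EpochRecord]]:
    """Mini-batch Adam training with cross-entropy loss.

    Images are raw (N, 3, H, W) float arrays in [0, 255]; normalisation
    constants default to the training split's own statistics. Fully seeded:
    data order, flips and weight initialisation (the caller seeds the
    model) are all reproducible.
    """
    if len(train_images) == 0:
        raise ValueError("empty training set")
    if mean is None or std is None:
        mean, std = normalization_constants(train_images)
    mean = mean.astype(np.float32)
    std = std.astype(np.float32)
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    val_norm = np.stack([
        augment(im, mean, std, train=False) for im in val_images
    ]).astype(np.float32) if len(val_images) else np.empty((0,) + train_images.shape[1:])

    records: list[EpochRecord] = []
    n = len(train_images)
    for epoch in range(1, config.epochs + 1):
        model.train()
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            batch_idx = order[start : start + config.batch_size]
            batch = np.stack([
                augment(train_images[i], mean, std, train=True, rng=rng,
                        hflip=config.hflip)
                for i in batch_idx
            ]).astype(np.float32)
            opt.zero_grad()
            loss = softmax_cross_entropy(model(Tensor(batch)),
                                         train_labels[batch_idx])
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        val_acc = _accuracy(model, val_norm, val_labels) if len(val_norm) else 0.0
        records.append(EpochRecord(epoch=epoch,
                                   train_loss=float(np.mean(losses)),
                                   val_accuracy=val_acc))
        if (config.early_stop_accuracy is not None
                and val_acc >= config.early_stop_accuracy):
            break
    return model, records


def _population_var(x: np.ndarray) -> float:
    return float(np.var(np.asarray(x, dtype=np.float64)))  # divide-by-N


def stability_metrics(records, window: int | None = 10) -> StabilityReport:
    """Mean and population variance/std of the validation-accuracy
    sequence, overall and over the first/last `window` epochs.

    Accepts a list of EpochRecord or a plain accuracy sequence. Pass
    ``window=None`` to skip the windowed statistics on short runs.
    """
    acc = np.asarray([
        r.val_accuracy if isinstance(r, EpochRecord) else float(r)
        for r in records
    ], dtype=np.float64)
    if acc.size < 2:
        raise ValueError("need at least two epochs")
    first10 = last10 = None
    if window is not None:
        if acc.size < 2 * window:
            raise ValueError(
                f"windowed variances need >= {2 * window} epochs, got {acc.size}"
            )
        first10 = _population_var(acc[:window])
        last10 = _population_var(acc[-window:])
    return StabilityReport(
        mean_accuracy=float(acc.mean()),
        overall_std=float(np.std(acc)),
        overall_variance=_population_var(acc),
        first10_variance=first10,
        last10_variance=last10,
    )


def macro_metrics(confusion: np.ndarray) -> tuple[float, float, float]:
    """Macro-averaged precision, recall, F1 from a confusion matrix
    (rows = true class). Empty denominators contribute 0 for that class."""
    confusion = np.asarray(confusion, dtype=np.float64)
    tp = np.diag(confusion)
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(confusion.sum(axis=0) > 0,
                             tp / confusion.sum(axis=0), 0.0)
        recall = np.where(confusion.sum(axis=1) > 0,
                          tp / confusion.sum(axis=1), 0.0)
        f1 = np.where(precision + recall > 0,
                      2 * precision * recall / (precision + recall), 0.0)
    return float(precision.mean()), float(recall.mean()), float(f1.mean())


def evaluate_model(model: ResNet, test_images: np.ndarray,
                   test_labels: np.ndarray, mean: np.ndarray, std: np.ndarray,
                   rounds: int = 10, seed: int = 0,
                   num_classes: int = 3) -> EvalReport:
    """Deterministic test-set evaluation plus `rounds` bootstrap rounds.

    The headline metrics (accuracy, confusion matrix, macro scores) come
    from one deterministic pass over the full test set. Round accuracies
    are computed on seeded bootstrap resamples of the prediction pairs and
    summarised by their population variance.
    """
    if len(test_images) == 0:
        raise ValueError("empty test set")
    norm = np.stack([
        augment(im, mean, std, train=False) for im in test_images
    ]).astype(np.float32)
    preds = model.predict(norm)
    confusion = _sk_confusion(test_labels, preds,
                              labels=np.arange(num_classes))
    accuracy = float(np.trace(confusion) / confusion.sum())
    precision, recall, f1 = macro_metrics(confusion)
    rng = np.random.default_rng(seed)
    round_accs = []
    for _ in range(rounds):
        idx = rng.integers(0, len(preds), len(preds))
        round_accs.append(float((preds[idx] == test_labels[idx]).mean()))
    return EvalReport(
        accuracy=accuracy,
        macro_precision=precision,
        macro_recall=recall,
        macro_f1=f1,
        confusion=confusion,
        round_accuracies=tuple(round_accs),
        mean_variance=_population_var(round_accs),
        rounds=rounds,
        round_mode="bootstrap",
    )


def compare_attention_variants(images: np.ndarray, labels: np.ndarray,
                               specs: list[ModelSpec], config: TrainConfig,
                               stability_window: int | None = 10,
                               rounds: int = 10) -> pd.DataFrame:
    """Train and evaluate each attention variant on a common data partition.

    Every variant shares the same split, the same seeds and the same
    normalisation constants, so rows differ only by architecture.
    """
    tr, va, te = stratified_split(labels, config.split_ratios, config.seed)
    mean, std = normalization_constants(images[tr])
    rows = []
    for spec in specs:
        model = build_classifier(spec, seed=config.seed)
        model, records = train_model(model, images[tr], labels[tr],
                                     images[va], labels[va], config,
                                     mean=mean, std=std)
        stab = stability_metrics(records, window=stability_window)
        ev = evaluate_model(model, images[te], labels[te], mean, std,
                            rounds=rounds, seed=config.seed,
                            num_classes=spec.num_classes)
        rows.append({
            "attention": spec.attention,
            "epochs_run": len(records),
            "mean_accuracy": stab.mean_accuracy,
            "overall_std": stab.overall_std,
            "overall_variance": stab.overall_variance,
            "first10_variance": stab.first10_variance,
            "last10_variance": stab.last10_variance,
            "test_accuracy": ev.accuracy,
            "macro_precision": ev.macro_precision,
            "macro_recall": ev.macro_recall,
            "macro_f1": ev.macro_f1,
            "mean_variance": ev.mean_variance,
        })
    return pd.DataFrame(rows)
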