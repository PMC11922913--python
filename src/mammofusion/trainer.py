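"""Dataset handling, preprocessing protocol and the training/evaluation loop.

Images arrive as 8-bit grayscale or RGB files in a two-class folder layout
(``benign/``, ``malignant/``) or as a CSV manifest, are resized bilinearly to
the model's input side, replicated to three channels, and normalized to
[0, 1] by dividing by 255.  The dataset is split 80/10/10 into train,
validation and test partitions (stratified by class, seeded).  Training
minimizes binary cross-entropy with mini-batch Adam; every source of
randomness (shuffling, weight init, dropout, augmentation) flows from the run
seed.  The positive class is malignant (label 1) and probabilities at or
above the decision threshold count as positive.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from PIL import Image
from scipy.ndimage import rotate as nd_rotate

from .errors import InvalidConfigError, InvalidInputError
from .metrics import ConfusionCounts, MetricSet, compute_metrics, confusion
from .rdn import RDNNetwork

__all__ = [
    "LabeledDataset",
    "SplitConfig",
    "TrainConfig",
    "TrainHistory",
    "EvalReport",
    "LABEL_NAMES",
    "load_dataset",
    "split_dataset",
    "preprocess_batch",
    "augment",
    "train",
    "evaluate",
    "save_weights",
    "load_weights",
]

logger = logging.getLogger(__name__)

LABEL_NAMES = {0: "benign", 1: "malignant"}
_NAME_TO_LABEL = {"benign": 0, "malignant": 1, "0": 0, "1": 1}
_IMAGE_EXTS = {".png", ".jpg", ".jpeg"}

ImageSource = Union[str, Path, np.ndarray]


# ---------------------------------------------------------------------------
# dataset container and loading
# ---------------------------------------------------------------------------


@dataclass
class LabeledDataset:
    """Items of (identifier, image source, binary label)."""

    items: List[Tuple[str, ImageSource, int]]

    def __post_init__(self) -> None:
        ids = [i for i, _, _ in self.items]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise InvalidInputError(f"duplicate identifiers in dataset: {dupes[:5]}")
        for _, _, label in self.items:
            if label not in (0, 1):
                raise InvalidInputError(f"labels must be binary, got {label!r}")

    def __len__(self) -> int:
        return len(self.items)

    @property
    def class_counts(self) -> dict:
        counts = {0: 0, 1: 0}
        for _, _, label in self.items:
            counts[label] += 1
        return counts

    @property
    def labels(self) -> np.ndarray:
        return np.array([label for _, _, label in self.items], dtype=int)

    def images(self) -> List[np.ndarray]:
        """Materialize every image source as an 8-bit array."""
        return [_read_image(src) for _, src, _ in self.items]

    def subset(self, indices: Sequence[int]) -> "LabeledDataset":
        return LabeledDataset(items=[self.items[i] for i in indices])


def _read_image(src: ImageSource) -> np.ndarray:
    if isinstance(src, np.ndarray):
        return src
    with Image.open(src) as im:
        return np.asarray(im.convert("L"))


def load_dataset(source: Union[str, Path]) -> LabeledDataset:
    """Index a two-class image folder tree or a CSV manifest.

    A folder must contain ``benign/`` and/or ``malignant/`` subfolders of
    PNG/JPEG files; a ``.csv`` manifest must have ``path`` and ``label``
    columns (paths relative to the manifest).  Unreadable files are skipped
    with a logged count; zero readable images is a fatal error.
    """
    source = Path(source)
    items: List[Tuple[str, ImageSource, int]] = []
    skipped = 0

    def try_add(identifier: str, path: Path, label: int) -> None:
        nonlocal skipped
        try:
            with Image.open(path) as im:
                im.verify()
        except Exception:
            logger.warning("skipping unreadable image %s", path)
            skipped += 1
            return
        items.append((identifier, path, label))

    if source.suffix.lower() == ".csv":
        with open(source, newline="") as fh:
            reader = csv.DictReader(fh)
            if not reader.fieldnames or not {"path", "label"} <= set(reader.fieldnames):
                raise InvalidInputError("manifest must have 'path' and 'label' columns")
            for row in reader:
                name = row["label"].strip().lower()
                if name not in _NAME_TO_LABEL:
                    raise InvalidInputError(f"unknown label value {row['label']!r}")
                path = (source.parent / row["path"]).resolve()
                try_add(row["path"], path, _NAME_TO_LABEL[name])
    elif source.is_dir():
        for class_name, label in (("benign", 0), ("malignant", 1)):
            class_dir = source / class_name
            if not class_dir.is_dir():
                continue
            for path in sorted(class_dir.rglob("*")):
                if path.suffix.lower() in _IMAGE_EXTS:
                    try_add(str(path.relative_to(source)), path, label)
    else:
        raise InvalidInputError(f"dataset source {source} is neither a folder nor a CSV")

    if skipped:
        logger.warning("skipped %d unreadable image(s)", skipped)
    if not items:
        raise InvalidInputError(f"no readable images found under {source}")
    ds = LabeledDataset(items=items)
    logger.info("loaded %d images, class counts %s", len(ds), ds.class_counts)
    return ds


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SplitConfig:
    """Train/validation/test fractions (default 80/10/10), seeded, stratified."""

    fractions: tuple = (0.8, 0.1, 0.1)
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if len(self.fractions) != 3 or any(not 0 < f < 1 for f in self.fractions):
            raise InvalidConfigError(f"each fraction must be in (0, 1), got {self.fractions}")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise InvalidConfigError(f"fractions must sum to 1, got {self.fractions}")


def _partition_sizes(n: int, fractions: tuple) -> Tuple[int, int, int]:
    # round val/test; the remainder goes to train
    n_val = int(round(fractions[1] * n))
    n_test = int(round(fractions[2] * n))
    n_train = n - n_val - n_test
    return n_train, n_val, n_test


def split_dataset(
    ds: LabeledDataset, cfg: SplitConfig = None
) -> Tuple[LabeledDataset, LabeledDataset, LabeledDataset]:
    """Disjoint, exhaustive train/val/test partition of a dataset.

    Partition sizes are ``round(fraction * n)`` for validation and test with
    the remainder assigned to train; stratified mode applies the same
    rounding per class.  Deterministic for a fixed seed.
    """
    cfg = cfg or SplitConfig()
    if len(ds) == 0:
        raise InvalidInputError("cannot split an empty dataset")
    rng = np.random.default_rng(cfg.seed)

    stratified = cfg.stratified
    if stratified:
        smallest = min(c for c in ds.class_counts.values() if c > 0)
        if smallest < 3:
            logger.warning(
                "a class has fewer items (%d) than partitions; degrading to "
                "unstratified splitting", smallest,
            )
            stratified = False

    def split_indices(indices: np.ndarray):
        perm = rng.permutation(indices)
        n_train, n_val, n_test = _partition_sizes(len(perm), cfg.fractions)
        return (
            perm[:n_train],
            perm[n_train : n_train + n_val],
            perm[n_train + n_val :],
        )

    labels = ds.labels
    if stratified:
        parts = [[], [], []]
        for cls in (0, 1):
            cls_idx = np.flatnonzero(labels == cls)
            if cls_idx.size == 0:
                continue
            for part, chunk in zip(parts, split_indices(cls_idx)):
                part.extend(chunk.tolist())
        train_idx, val_idx, test_idx = (sorted(p) for p in parts)
    else:
        train_idx, val_idx, test_idx = (
            sorted(p.tolist()) for p in split_indices(np.arange(len(ds)))
        )
    return ds.subset(train_idx), ds.subset(val_idx), ds.subset(test_idx)


# ---------------------------------------------------------------------------
# preprocessing and augmentation
# ---------------------------------------------------------------------------


def preprocess_batch(images: Sequence[np.ndarray], target_size: int = 128) -> np.ndarray:
    """Resize, replicate to 3 channels and scale 8-bit images to [0, 1].

    Accepts 8-bit integer arrays (any size, 2-D or RGB) or already-normalized
    float arrays in [0, 1]; the operation is idempotent on normalized,
    already-sized input.  Returns a (n, target_size, target_size, 3) float
    stack.
    """
    target_shape = (target_size, target_size)
    out = np.empty((len(images), target_size, target_size, 3))
    for i, img in enumerate(images):
        a = np.asarray(img)
        is_float = np.issubdtype(a.dtype, np.floating)
        if is_float:
            if a.size and (a.min() < 0.0 or a.max() > 1.0):
                raise InvalidInputError(
                    "float input must already be normalized to [0, 1]; "
                    "8-bit integer input is scaled by 1/255"
                )
            # already-normalized, already-sized input passes through unchanged
            if a.shape == target_shape + (3,):
                out[i] = a
                continue
            if a.shape == target_shape:
                out[i] = a[..., None].repeat(3, axis=2)
                continue
            a8 = np.clip(np.round(a * 255.0), 0, 255).astype(np.uint8)
        elif np.issubdtype(a.dtype, np.integer) or a.dtype == bool:
            if a.size and (a.min() < 0 or a.max() > 255):
                raise InvalidInputError("integer input must be 8-bit (values in [0, 255])")
            a8 = a.astype(np.uint8)
        else:
            raise InvalidInputError(f"unsupported image dtype {a.dtype}")

        if a8.ndim == 3 and a8.shape[2] in (3, 4):
            a8 = np.asarray(Image.fromarray(a8[..., :3]).convert("L"))
        elif a8.ndim != 2:
            raise InvalidInputError(f"cannot interpret image of shape {a.shape}")

        if a8.shape != target_shape:
            a8 = np.asarray(
                Image.fromarray(a8).resize(target_shape, Image.BILINEAR)
            )
        out[i] = (a8 / 255.0)[..., None].repeat(3, axis=2)
    return out


def augment(image: np.ndarray, seed: int) -> np.ndarray:
    """Label-preserving augmentation: horizontal flip (p=0.5), rotation ±10°.

    Deterministic per seed; the output has the input's shape.
    """
    rng = np.random.default_rng(seed)
    out = np.asarray(image, dtype=float)
    if rng.random() < 0.5:
        out = out[:, ::-1].copy()
    angle = rng.uniform(-10.0, 10.0)
    out = nd_rotate(out, angle, axes=(1, 0), reshape=False, order=1, mode="nearest")
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings; plumbing defaults, freely overridable."""

    epochs: int = 10
    batch_size: int = 32
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    seed: int = 0
    target_size: int = 128
    augment: bool = False
    class_weighted: bool = False

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise InvalidConfigError(
                "epochs >= 1, batch_size >= 1 and learning_rate > 0 required"
            )
        if self.optimizer not in ("adam", "sgd"):
            raise InvalidConfigError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class TrainHistory:
    """Per-epoch train/validation loss and accuracy series."""

    train_loss: List[float] = field(default_factory=list)
    train_accuracy: List[float] = field(default_factory=list)
    val_loss: List[float] = field(default_factory=list)
    val_accuracy: List[float] = field(default_factory=list)

    def to_csv(self, path: Union[str, Path]) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["epoch", "train_loss", "train_accuracy", "val_loss", "val_accuracy"])
            for i in range(len(self.train_loss)):
                writer.writerow(
                    [i + 1, self.train_loss[i], self.train_accuracy[i],
                     self.val_loss[i], self.val_accuracy[i]]
                )


class _Adam:
    def __init__(self, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m, self.v, self.t = {}, {}, 0

    def step(self, params, grads):
        self.t += 1
        for (i, name, p), (_, _, g) in zip(params, grads):
            key = (i, name)
            m = self.m.setdefault(key, np.zeros_like(p))
            v = self.v.setdefault(key, np.zeros_like(p))
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class _SGD:
    def __init__(self, lr):
        self.lr = lr

    def step(self, params, grads):
        for (_, _, p), (_, _, g) in zip(params, grads):
            p -= self.lr * g


def _bce_loss(probs: np.ndarray, y: np.ndarray, weights: np.ndarray) -> float:
    p = np.clip(probs, 1e-12, 1.0 - 1e-12)
    return float(-np.sum(weights * (y * np.log(p) + (1 - y) * np.log(1 - p))) / weights.sum())


def train(
    net: RDNNetwork,
    train_ds: LabeledDataset,
    val_ds: Optional[LabeledDataset],
    cfg: TrainConfig = None,
) -> Tuple[RDNNetwork, TrainHistory]:
    """Train a network by mini-batch gradient descent on binary cross-entropy.

    The per-batch gradient is injected at the output pre-activation as
    ``(p - y) / batch_size`` (the combined sigmoid/cross-entropy form).
    Shuffling, dropout and augmentation all derive from ``cfg.seed``.
    Training aborts with a diagnostic if the loss becomes non-finite.
    """
    cfg = cfg or TrainConfig()
    if len(train_ds) == 0:
        raise InvalidInputError("training dataset is empty")
    if net.input_shape[0] != cfg.target_size:
        raise InvalidInputError(
            f"network input size {net.input_shape[0]} != cfg.target_size {cfg.target_size}"
        )
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    dropout_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))

    X = preprocess_batch(train_ds.images(), cfg.target_size)
    y = train_ds.labels.astype(float)
    if val_ds is not None and len(val_ds):
        Xv = preprocess_batch(val_ds.images(), cfg.target_size)
        yv = val_ds.labels.astype(float)
    else:
        Xv = yv = None

    if cfg.class_weighted:
        counts = train_ds.class_counts
        n = len(train_ds)
        w_by_class = {c: n / (2.0 * max(counts[c], 1)) for c in (0, 1)}
        sample_w = np.array([w_by_class[int(t)] for t in y])
    else:
        sample_w = np.ones_like(y)

    opt = _Adam(cfg.learning_rate) if cfg.optimizer == "adam" else _SGD(cfg.learning_rate)
    history = TrainHistory()

    for epoch in range(cfg.epochs):
        order = rng.permutation(len(X))
        epoch_loss, epoch_correct, seen = 0.0, 0, 0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb = X[idx]
            if cfg.augment:
                xb = np.stack(
                    [augment(im, seed=int(rng.integers(2**31))) for im in xb]
                )
            yb = y[idx]
            wb = sample_w[idx]
            probs = net.forward(xb, train_mode=True, rng=dropout_rng)
            loss = _bce_loss(probs, yb, wb)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged: non-finite loss at epoch {epoch + 1}"
                )
            grad = (wb * (probs - yb) / wb.sum()).reshape(-1, 1)
            net.backward(grad, from_preactivation=True)
            opt.step(net.parameters(), net.gradients())
            epoch_loss += loss * len(idx)
            epoch_correct += int(np.sum((probs >= 0.5) == (yb == 1)))
            seen += len(idx)

        history.train_loss.append(epoch_loss / seen)
        history.train_accuracy.append(epoch_correct / seen)
        if Xv is not None:
            pv = net.forward(Xv, train_mode=False)
            history.val_loss.append(_bce_loss(pv, yv, np.ones_like(yv)))
            history.val_accuracy.append(float(np.mean((pv >= 0.5) == (yv == 1))))
        else:
            history.val_loss.append(float("nan"))
            history.val_accuracy.append(float("nan"))
        logger.info(
            "epoch %d/%d: train loss %.4f acc %.3f, val loss %.4f acc %.3f",
            epoch + 1, cfg.epochs,
            history.train_loss[-1], history.train_accuracy[-1],
            history.val_loss[-1], history.val_accuracy[-1],
        )
    return net, history


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


@dataclass
class EvalReport:
    """Confusion counts, derived metrics and per-sample probabilities."""

    counts: ConfusionCounts
    metrics: MetricSet
    probabilities: np.ndarray
    labels: np.ndarray
    threshold: float = 0.5
    schema_version: int = 1

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "threshold": self.threshold,
            "counts": {
                "tp": self.counts.tp,
                "tn": self.counts.tn,
                "fp": self.counts.fp,
                "fn": self.counts.fn,
            },
            "metrics": self.metrics.as_dict(),
            "probabilities": [float(p) for p in self.probabilities],
            "labels": [int(t) for t in self.labels],
        }


def evaluate(
    net: RDNNetwork,
    ds: LabeledDataset,
    threshold: float = 0.5,
    target_size: Optional[int] = None,
    batch_size: int = 64,
) -> EvalReport:
    """Threshold network probabilities and compute the five diagnostic metrics.

    Probabilities at or above ``threshold`` predict malignant (positive).
    """
    if len(ds) == 0:
        raise InvalidInputError("evaluation dataset is empty")
    size = target_size or net.input_shape[0]
    X = preprocess_batch(ds.images(), size)
    probs = np.concatenate(
        [net.forward(X[i : i + batch_size]) for i in range(0, len(X), batch_size)]
    )
    y = ds.labels
    preds = (probs >= threshold).astype(int)
    cc = confusion(y, preds)
    return EvalReport(
        counts=cc, metrics=compute_metrics(cc), probabilities=probs, labels=y,
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def save_weights(net: RDNNetwork, path: Union[str, Path]) -> None:
    """Write network weights (and the architecture config) to an .npz file."""
    state = net.get_weights()
    meta = {}
    if net.config is not None:
        c = net.config
        meta = {
            "input_size": c.input_size,
            "input_channels": c.input_channels,
            "block_widths": np.array(c.block_widths),
            "use_batch_norm": int(c.use_batch_norm),
            "dropout_rate": c.dropout_rate,
            "seed": c.seed,
        }
    np.savez(path, **{f"w/{k}": v for k, v in state.items()},
             **{f"meta/{k}": v for k, v in meta.items()})


def load_weights(path: Union[str, Path]) -> RDNNetwork:
    """Rebuild a network from a weights file written by :func:`save_weights`."""
    from .rdn import RDNConfig, build_rdn

    with np.load(path) as data:
        meta = {k[5:]: data[k] for k in data.files if k.startswith("meta/")}
        state = {k[2:]: data[k] for k in data.files if k.startswith("w/")}
    if not meta:
        raise InvalidInputError(f"{path} does not contain an architecture config")
    cfg = RDNConfig(
        input_size=int(meta["input_size"]),
        input_channels=int(meta["input_channels"]),
        block_widths=tuple(int(w) for w in meta["block_widths"]),
        use_batch_norm=bool(int(meta["use_batch_norm"])),
        dropout_rate=float(meta["dropout_rate"]),
        seed=int(meta["seed"]),
    )
    net = build_rdn(cfg)
    net.set_weights(state)
    return net
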