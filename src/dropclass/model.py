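"""Residual-network droplet classifier: build, train, predict, filter.

The classifier maps a preprocessed (n, 55, 55) stack to three classes
(Empty/0, Single/1, Multiple/2).  Two architectures share the same I/O
contract:

* ``arch_depth="small"`` — an 18-layer-style residual network scaled for
  desk-size experiments: a 3x3 stem, two strided basic residual blocks,
  global average pooling and a 3-way softmax head.
* ``arch_depth=50`` — the standard 50-layer bottleneck residual network
  (stages 3-4-6-3, x4 expansion) with the grayscale input replicated to
  three channels.

Training follows the recipe: categorical cross-entropy minimized by
mini-batch stochastic gradient descent at learning rate 0.001 for 6 epochs
with batches of 160, on a seeded stratified 95/5 train/validation split.
The loss is summed over each mini-batch, so the effective step size grows
with the batch size (large batches destabilize training, small ones take
small steps).  No augmentation and no pretrained weights by default.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .imgio import U16_MAX

log = logging.getLogger("dropclass.model")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 6
    batch_size: int = 160
    learning_rate: float = 0.001
    momentum: float = 0.0
    validation_fraction: float = 0.05
    n_classes: int = 3
    input_side: int = 55
    arch_depth: object = "small"  # "small" | 50
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.validation_fraction < 1):
            raise ValueError("validation_fraction must lie in (0, 1)")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")
        if self.arch_depth not in ("small", 50):
            raise ValueError('arch_depth must be "small" or 50')
        if self.arch_depth == 50 and self.input_side < 32:
            raise ValueError("depth-50 variant needs input_side >= 32")


@dataclass
class Prediction:
    """Predicted class with a 0-100 confidence (100 x max class probability)."""

    label: int
    confidence: float
    probabilities: np.ndarray

    def __post_init__(self):
        self.probabilities = np.asarray(self.probabilities, dtype=np.float64)
        assert self.label == int(np.argmax(self.probabilities))


class ResNetClassifier:
    """A residual CNN over single-channel input stacks."""

    def __init__(self, cfg: TrainConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        if cfg.arch_depth == "small":
            self.in_channels = 1
            self.net = nn.Sequential(
                nn.Conv2d(1, 16, 3, 1, 1, rng),
                nn.BatchNorm2d(16),
                nn.ReLU(),
                nn.MaxPool2d(2, 2),
                nn.BasicBlock(16, 32, 2, rng),
                nn.BasicBlock(32, 64, 2, rng),
                nn.GlobalAvgPool(),
                nn.Dense(64, cfg.n_classes, rng),
            )
        else:
            self.in_channels = 3  # grayscale replicated to 3 channels
            layers = [
                nn.Conv2d(3, 64, 7, 2, 3, rng),
                nn.BatchNorm2d(64),
                nn.ReLU(),
                nn.MaxPool2d(3, 2, 1),
            ]
            in_ch = 64
            for mid, blocks, stride in ((64, 3, 1), (128, 4, 2), (256, 6, 2), (512, 3, 2)):
                for b in range(blocks):
                    layers.append(nn.BottleneckBlock(in_ch, mid, stride if b == 0 else 1, rng))
                    in_ch = mid * nn.BottleneckBlock.EXPANSION
            layers += [nn.GlobalAvgPool(), nn.Dense(in_ch, cfg.n_classes, rng)]
            self.net = nn.Sequential(*layers)

    def _prepare(self, images) -> np.ndarray:
        x = np.asarray(images, dtype=nn.DTYPE)
        if x.ndim == 2:
            x = x[None]
        if x.ndim != 3 or x.shape[1] != self.cfg.input_side or x.shape[2] != self.cfg.input_side:
            raise ValueError(
                f"expected (n, {self.cfg.input_side}, {self.cfg.input_side}) input, got {x.shape}"
            )
        x = x / np.float32(U16_MAX)  # fixed affine to unit scale
        x = x[:, None, :, :]
        if self.in_channels == 3:
            x = np.repeat(x, 3, axis=1)
        return x

    def forward_logits(self, images, train: bool = False) -> np.ndarray:
        return self.net.forward(self._prepare(images), train)

    def predict_proba(self, images, batch_size: int = 256) -> np.ndarray:
        images = np.asarray(images, dtype=nn.DTYPE)
        if images.ndim == 2:
            images = images[None]
        out = [
            nn.softmax(self.forward_logits(images[i : i + batch_size], train=False).astype(np.float64))
            for i in range(0, len(images), batch_size)
        ]
        return np.concatenate(out, axis=0)


def build_classifier(cfg: TrainConfig = TrainConfig()) -> ResNetClassifier:
    """Construct the (untrained) classifier; fixed seed gives deterministic
    initial weights."""
    return ResNetClassifier(cfg)


def _stratified_split(labels, validation_fraction, rng):
    labels = np.asarray(labels)
    train_idx, val_idx = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        n_val = int(round(len(idx) * validation_fraction))
        val_idx.extend(idx[:n_val])
        train_idx.extend(idx[n_val:])
    return np.array(sorted(train_idx), dtype=int), np.array(sorted(val_idx), dtype=int)


def _epoch_eval(model, x, y, batch_size=512):
    """Loss (per-sample mean) and accuracy in inference mode."""
    losses, correct = 0.0, 0
    for i in range(0, len(x), batch_size):
        logits = model.forward_logits(x[i : i + batch_size], train=False)
        loss, _, probs = nn.cross_entropy(logits, y[i : i + batch_size])
        losses += loss
        correct += int((probs.argmax(axis=1) == y[i : i + batch_size]).sum())
    return losses / len(x), correct / len(x)


def train_classifier(images, labels, cfg: TrainConfig = TrainConfig()):
    """Train on preprocessed labeled images; returns (model, history).

    ``history`` is a list of per-epoch dicts with train/validation loss
    (per-sample mean) and accuracy; epoch 0 records the untrained state.
    """
    x = np.asarray(images, dtype=nn.DTYPE)
    y = np.asarray(labels, dtype=np.int64)
    if x.ndim != 3 or len(x) != len(y):
        raise ValueError("images must be (n, side, side) aligned with labels")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < cfg.n_classes:
        raise ValueError(f"need >= 1 example of each of {cfg.n_classes} classes, got {classes}")
    if counts.max() != counts.min():
        log.warning("class counts %s are imbalanced; training proceeds as given", dict(zip(classes.tolist(), counts.tolist())))

    rng = np.random.default_rng(cfg.seed)
    train_idx, val_idx = _stratified_split(y, cfg.validation_fraction, rng)
    if len(np.unique(y[train_idx])) < cfg.n_classes:
        raise ValueError("a class is missing from the training split")
    x_tr, y_tr = x[train_idx], y[train_idx]
    x_val, y_val = x[val_idx], y[val_idx]

    model = build_classifier(cfg)
    opt = nn.SGD(model.net.all_params(), lr=cfg.learning_rate, momentum=cfg.momentum)

    history = []

    def record(epoch, tr_loss, tr_acc):
        entry = {"epoch": epoch, "train_loss": tr_loss, "train_accuracy": tr_acc}
        if len(x_val):
            val_loss, val_acc = _epoch_eval(model, x_val, y_val)
            entry.update({"val_loss": val_loss, "val_accuracy": val_acc})
        history.append(entry)
        log.info(
            "epoch %d: train loss %.4f acc %.3f%s",
            epoch,
            tr_loss,
            tr_acc,
            f" | val loss {entry.get('val_loss', float('nan')):.4f} acc {entry.get('val_accuracy', float('nan')):.3f}"
            if len(x_val)
            else "",
        )

    record(0, *_epoch_eval(model, x_tr, y_tr))
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(len(x_tr))
        loss_sum, correct = 0.0, 0
        for i in range(0, len(order), cfg.batch_size):
            batch = order[i : i + cfg.batch_size]
            opt.zero_grad()
            logits = model.forward_logits(x_tr[batch], train=True)
            loss, dlogits, probs = nn.cross_entropy(logits, y_tr[batch])
            model.net.backward(dlogits)
            opt.step()
            loss_sum += loss
            correct += int((probs.argmax(axis=1) == y_tr[batch]).sum())
        # epoch training metrics are the running averages over the epoch's
        # mini-batches (train mode), not a separate full pass
        record(epoch, loss_sum / len(order), correct / len(order))
    return model, history


def predict(model: ResNetClassifier, images) -> list[Prediction]:
    """One Prediction per image, order preserved; deterministic given
    fixed weights.  Wrong spatial size is an error (no silent resize)."""
    probs = model.predict_proba(images)
    return [
        Prediction(label=int(p.argmax()), confidence=100.0 * float(p.max()), probabilities=p)
        for p in probs
    ]


def filter_by_confidence(preds, threshold: float):
    """Keep predictions with confidence >= threshold (a 0-100 percentage);
    returns (retained predictions, retained fraction)."""
    if not (0 <= threshold <= 100):
        raise ValueError("threshold must lie in [0, 100]")
    kept = [p for p in preds if p.confidence >= threshold]
    frac = len(kept) / len(preds) if preds else 0.0
    return kept, frac


def save_model(model: ResNetClassifier, out_dir, preprocess_config=None) -> None:
    """Checkpoint: weights.npz plus a JSON sidecar of the configs."""
    os.makedirs(os.fspath(out_dir), exist_ok=True)
    arrays = model.net.state_arrays()
    np.savez(os.path.join(out_dir, "weights.npz"), *arrays)
    sidecar = {"train_config": asdict(model.cfg)}
    if preprocess_config is not None:
        sidecar["preprocess_config"] = asdict(preprocess_config)
    with open(os.path.join(out_dir, "config.json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_model(model_dir) -> ResNetClassifier:
    with open(os.path.join(model_dir, "config.json")) as fh:
        sidecar = json.load(fh)
    cfg = TrainConfig(**sidecar["train_config"])
    model = build_classifier(cfg)
    with np.load(os.path.join(model_dir, "weights.npz")) as data:
        arrays = [data[f"arr_{i}"] for i in range(len(data.files))]
    model.net.load_state_arrays(arrays)
    return model
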