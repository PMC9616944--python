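"""The compact lesion-classification CNN.

Architecture (fixed stack, square inputs, default 96x96x3):

    Conv(32, 3x3, ReLU, same) + BN
    MaxPool 3x3 (stride 3)          # 96 -> 32: shrinks the grid quickly
    Dropout 0.25
    Conv(64, 3x3, ReLU, same)
    Conv(64, 3x3, ReLU, same) + BN
    MaxPool 2x2                     # 32 -> 16
    Dropout 0.25
    Conv(128, 3x3, ReLU, same)
    Conv(128, 3x3, ReLU, same) + BN
    MaxPool 2x2                     # 16 -> 8
    Dropout 0.25
    Flatten -> Dense(1024, ReLU) + BN -> Dropout 0.5 -> Dense(n_classes, softmax)

Training: Adam on categorical cross-entropy, batch size 32, learning rate
decayed linearly across the epoch budget (default 1e-3 -> 1e-5), feeding on
the random-transform augmentation stream so each epoch sees exactly as many
samples as the input set.  Implemented in NumPy; with a fixed seed two runs
produce identical weights.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .errors import ConfigurationError, DivergenceError, ValidationError
from .preprocess import AugmentPolicy, random_transform_stream

#: (kind, arg) description of the fixed layer stack; conv entries carry
#: (filters, batch_norm_after) so the shape audit can replay it.
LAYER_STACK = (
    ("conv", 32, True),
    ("pool", 3),
    ("dropout", 0.25),
    ("conv", 64, False),
    ("conv", 64, True),
    ("pool", 2),
    ("dropout", 0.25),
    ("conv", 128, False),
    ("conv", 128, True),
    ("pool", 2),
    ("dropout", 0.25),
    ("flatten",),
    ("dense", 1024, True),
    ("dropout", 0.5),
    ("dense_out",),
)


@dataclass(frozen=True)
class CnnSpec:
    """Architecture + training hyperparameters of the lesion CNN."""

    input_side: int = 96
    input_depth: int = 3
    n_classes: int = 7
    optimizer: str = "adam"
    loss: str = "categorical_crossentropy"
    epochs: int = 150
    batch_size: int = 32
    lr_start: float = 1e-3
    lr_end: float = 1e-5
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")
        side = self.input_side
        # pool chain is 3, 2, 2 -> the side must divide by 12 (96 -> 32 -> 16 -> 8)
        if side < 12 or side % 12 != 0:
            raise ConfigurationError(
                f"input_side {side} incompatible with the 3/2/2 pooling chain; "
                "use a multiple of 12 (e.g. 24, 48, 96)"
            )


@dataclass
class TrainingHistory:
    """Per-epoch loss/accuracy on the training and validation sets."""

    loss: list[float] = field(default_factory=list)
    accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)

    def save(self, path) -> None:
        with open(path, "w", newline="") as f:
            w = csv.writer(f)
            w.writerow(["epoch", "loss", "acc", "val_loss", "val_acc"])
            for e in range(len(self.loss)):
                w.writerow([e + 1, self.loss[e], self.accuracy[e],
                            self.val_loss[e], self.val_accuracy[e]])


def layer_output_shapes(spec: CnnSpec) -> list[tuple]:
    """(C, H, W) / (features,) after every entry of LAYER_STACK."""
    shape: tuple = (spec.input_depth, spec.input_side, spec.input_side)
    shapes = []
    for entry in LAYER_STACK:
        kind = entry[0]
        if kind == "conv":
            shape = (entry[1], shape[1], shape[2])
        elif kind == "pool":
            shape = (shape[0], shape[1] // entry[1], shape[2] // entry[1])
        elif kind == "flatten":
            shape = (int(np.prod(shape)),)
        elif kind == "dense":
            shape = (entry[1],)
        elif kind == "dense_out":
            shape = (spec.n_classes,)
        shapes.append(shape)
    return shapes


def build_cnn(spec: CnnSpec) -> nn.Sequential:
    """Instantiate the fixed layer stack with seeded He initialisation."""
    rng = np.random.default_rng(spec.seed)
    layers: list[nn.Layer] = []
    in_ch = spec.input_depth
    side = spec.input_side
    for entry in LAYER_STACK:
        kind = entry[0]
        if kind == "conv":
            filters, bn = entry[1], entry[2]
            layers.append(nn.Conv2D(in_ch, filters, rng=rng))
            layers.append(nn.ReLU())
            if bn:
                layers.append(nn.BatchNorm(filters))
            in_ch = filters
        elif kind == "pool":
            layers.append(nn.MaxPool(entry[1]))
            side //= entry[1]
        elif kind == "dropout":
            layers.append(nn.Dropout(entry[1], rng=rng))
        elif kind == "flatten":
            layers.append(nn.Flatten())
            in_ch = in_ch * side * side
        elif kind == "dense":
            layers.append(nn.Dense(in_ch, entry[1], rng=rng))
            layers.append(nn.ReLU())
            if entry[2]:
                layers.append(nn.BatchNorm(entry[1]))
            in_ch = entry[1]
        elif kind == "dense_out":
            layers.append(nn.Dense(in_ch, spec.n_classes, rng=rng))
    return nn.Sequential(layers)


def _check_inputs(images: np.ndarray, onehot: np.ndarray, spec: CnnSpec) -> None:
    if images.ndim != 4 or images.shape[1:] != (spec.input_side, spec.input_side, spec.input_depth):
        raise ValidationError(
            f"images must be (n, {spec.input_side}, {spec.input_side}, {spec.input_depth}), "
            f"got {images.shape}"
        )
    if onehot.ndim != 2 or onehot.shape != (len(images), spec.n_classes):
        raise ValidationError(
            f"labels must be one-hot (n, {spec.n_classes}), got {onehot.shape}"
        )
    if images.min() < 0.0 or images.max() > 1.0:
        raise ValidationError("images must be normalised to [0, 1]")


def _epoch_lr(spec: CnnSpec, epoch: int) -> float:
    if spec.epochs == 1:
        return spec.lr_start
    frac = epoch / (spec.epochs - 1)
    return spec.lr_start + (spec.lr_end - spec.lr_start) * frac


def evaluate_cnn(model: nn.Sequential, images: np.ndarray, onehot: np.ndarray,
                 batch_size: int = 64) -> tuple[float, float]:
    """(mean cross-entropy, accuracy) in inference mode."""
    losses, correct = [], 0
    for start in range(0, len(images), batch_size):
        xb = images[start : start + batch_size].transpose(0, 3, 1, 2).astype(np.float32)
        yb = onehot[start : start + batch_size]
        logits = model.forward(xb, training=False)
        loss, probs = model.loss_fn.forward(logits, yb)
        losses.append(loss * len(xb))
        correct += int((probs.argmax(1) == yb.argmax(1)).sum())
    n = len(images)
    return float(np.sum(losses) / n), correct / n


def train_cnn(
    spec: CnnSpec,
    images: np.ndarray,
    onehot: np.ndarray,
    val_images: np.ndarray | None = None,
    val_onehot: np.ndarray | None = None,
    policy: AugmentPolicy | None = None,
) -> tuple[nn.Sequential, TrainingHistory]:
    """Train the CNN on [0,1]-normalised images with one-hot labels.

    Each epoch consumes one pass of the augmentation stream (same sample
    count as the input) at the linearly decayed learning rate.  Training
    metrics are running means over the epoch's batches; validation metrics
    are computed in inference mode at the epoch end.
    """
    images = np.asarray(images, dtype=np.float64)
    onehot = np.asarray(onehot, dtype=np.float64)
    _check_inputs(images, onehot, spec)
    if policy is None:
        policy = AugmentPolicy(seed=spec.seed)

    model = build_cnn(spec)
    opt = nn.Adam(model, lr=spec.lr_start)
    history = TrainingHistory()
    n = len(images)
    has_val = val_images is not None and val_onehot is not None

    for epoch in range(spec.epochs):
        opt.lr = _epoch_lr(spec, epoch)
        epoch_policy = AugmentPolicy(
            **{**policy.__dict__, "seed": (policy.seed + epoch) % (2**31)}
        )
        stream = random_transform_stream(
            images, onehot, epoch_policy, spec.batch_size, epochs=1, shuffle=True
        )
        total_loss, total_correct = 0.0, 0
        for xb, yb in stream:
            x = xb.transpose(0, 3, 1, 2).astype(np.float32)
            logits = model.forward(x, training=True)
            loss, probs = model.loss_fn.forward(logits, yb)
            if not np.isfinite(loss):
                raise DivergenceError(epoch + 1)
            model.backward(model.loss_fn.backward())
            opt.step()
            total_loss += loss * len(xb)
            total_correct += int((probs.argmax(1) == yb.argmax(1)).sum())
        history.loss.append(total_loss / n)
        history.accuracy.append(total_correct / n)
        if has_val:
            vl, va = evaluate_cnn(model, np.asarray(val_images), np.asarray(val_onehot))
        else:
            vl, va = float("nan"), float("nan")
        history.val_loss.append(vl)
        history.val_accuracy.append(va)
    return model, history


def predict_cnn(model: nn.Sequential, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
    """Row-stochastic (n, n_classes) probability matrix."""
    images = np.asarray(images)
    n_classes = model.layers[-1].n_out
    if len(images) == 0:
        return np.zeros((0, n_classes))
    if images.ndim != 4 or images.shape[3] != 3:
        raise ValidationError(f"images must be (n, side, side, 3), got {images.shape}")
    out = []
    for start in range(0, len(images), batch_size):
        x = images[start : start + batch_size].transpose(0, 3, 1, 2).astype(np.float32)
        out.append(nn.softmax(model.forward(x, training=False)))
    return np.concatenate(out, axis=0)


def save_cnn(model: nn.Sequential, path) -> None:
    """Checkpoint trainable weights plus batch-norm running statistics."""
    arrays = {f"w{i}": w for i, w in enumerate(model.get_weights())}
    stats = {}
    for i, layer in enumerate(model.layers):
        if isinstance(layer, nn.BatchNorm):
            stats[f"bn{i}_mean"] = layer.running_mean
            stats[f"bn{i}_var"] = layer.running_var
    np.savez(path, **arrays, **stats)


def load_cnn(spec: CnnSpec, path) -> nn.Sequential:
    model = build_cnn(spec)
    with np.load(path) as data:
        weights = [data[f"w{i}"] for i in range(sum(1 for _ in model.parameters()))]
        model.set_weights(weights)
        for i, layer in enumerate(model.layers):
            if isinstance(layer, nn.BatchNorm):
                layer.running_mean = data[f"bn{i}_mean"]
                layer.running_var = data[f"bn{i}_var"]
    return model


def plot_history(history: TrainingHistory, path) -> None:
    """Learning-curve PNG: loss and accuracy vs epoch, train and validation."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    epochs = np.arange(1, len(history.loss) + 1)
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    ax1.plot(epochs, history.loss, label="train")
    if np.isfinite(history.val_loss).any():
        ax1.plot(epochs, history.val_loss, label="validation")
    ax1.set_xlabel("epoch"), ax1.set_ylabel("cross-entropy loss"), ax1.legend()
    ax2.plot(epochs, history.accuracy, label="train")
    if np.isfinite(history.val_accuracy).any():
        ax2.plot(epochs, history.val_accuracy, label="validation")
    ax2.set_xlabel("epoch"), ax2.set_ylabel("accuracy"), ax2.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
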