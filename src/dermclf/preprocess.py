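"""Resizing, normalisation, label encoding, augmentation and splitting.

Two augmentation flavours serve the two branches of the pipeline:

* the feature branch doubles the dataset once with a deterministic
  horizontal flip (:func:`augment_flip`), so 100 images/class become 200;
* the CNN branch draws a fresh random affine transform of every sample
  each epoch (:func:`random_transform_stream`), keeping the per-epoch
  sample count equal to the input count.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from .dataset import CLASS_CODES, LesionImage
from .errors import ConfigurationError, LabelError


@dataclass(frozen=True)
class LabelCodec:
    """Bidirectional mapping between class codes and one-hot vectors."""

    classes: tuple[str, ...] = CLASS_CODES

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def index(self, label: str) -> int:
        try:
            return self.classes.index(label)
        except ValueError:
            raise LabelError(f"unknown label {label!r}; known: {self.classes}") from None

    def encode(self, labels) -> np.ndarray:
        """Labels -> one-hot float matrix, rows in input order."""
        out = np.zeros((len(labels), self.n_classes), dtype=np.float64)
        for i, lab in enumerate(labels):
            out[i, self.index(lab)] = 1.0
        return out

    def decode(self, onehot_or_indices) -> list[str]:
        arr = np.asarray(onehot_or_indices)
        idx = arr.argmax(axis=1) if arr.ndim == 2 else arr.astype(int)
        return [self.classes[i] for i in idx]


def resize_image(img: LesionImage, side: int) -> LesionImage:
    """Bilinear resize to a square of ``side`` pixels (channels preserved)."""
    if side < 1:
        raise ConfigurationError(f"side must be >= 1, got {side}")
    if img.pixels.size == 0:
        raise ValueError("cannot resize an empty image")
    if img.pixels.shape[:2] == (side, side):
        return LesionImage(img.image_id, img.label, img.pixels.copy())
    resized = Image.fromarray(img.pixels).resize((side, side), Image.BILINEAR)
    return LesionImage(img.image_id, img.label, np.asarray(resized, dtype=np.uint8))


def normalize01(img: LesionImage | np.ndarray) -> np.ndarray:
    """Map 8-bit intensities v to v/255 in [0, 1] (float64)."""
    pixels = img.pixels if isinstance(img, LesionImage) else np.asarray(img)
    return pixels.astype(np.float64) / 255.0


def encode_labels(labels, codec: LabelCodec | None = None) -> np.ndarray:
    codec = codec or LabelCodec()
    return codec.encode(labels)


def augment_flip(images: list[LesionImage]) -> list[LesionImage]:
    """Originals followed by their left-right mirrors (ids suffixed ``_hf``)."""
    flipped = [
        LesionImage(f"{im.image_id}_hf", im.label, im.pixels[:, ::-1].copy())
        for im in images
    ]
    return list(images) + flipped


@dataclass(frozen=True)
class AugmentPolicy:
    """Random affine augmentation ranges for CNN training.

    Ranges are half-widths: rotation is drawn uniformly from
    [-rotation_range, +rotation_range] degrees, and so on.  Defaults are
    conventional mild ranges; a fully zeroed policy (flip off) is the
    identity, which the stream contract guarantees exactly.
    """

    horizontal_flip: bool = True
    rotation_range: float = 25.0   # degrees
    shear_range: float = 0.2       # dimensionless shear factor
    zoom_range: float = 0.2        # fractional zoom half-width
    width_shift: float = 0.1       # fraction of image width
    height_shift: float = 0.1      # fraction of image height
    seed: int = 0

    def __post_init__(self):
        for name in ("rotation_range", "shear_range", "zoom_range", "width_shift", "height_shift"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")

    @property
    def is_identity(self) -> bool:
        return not self.horizontal_flip and all(
            getattr(self, n) == 0
            for n in ("rotation_range", "shear_range", "zoom_range", "width_shift", "height_shift")
        )


def _random_affine(policy: AugmentPolicy, size_hw, rng: np.random.Generator):
    """Sample one affine map (matrix, offset) about the image centre."""
    h, w = size_hw
    angle = math.radians(rng.uniform(-policy.rotation_range, policy.rotation_range))
    shear = rng.uniform(-policy.shear_range, policy.shear_range)
    zoom = 1.0 + rng.uniform(-policy.zoom_range, policy.zoom_range)
    tx = rng.uniform(-policy.width_shift, policy.width_shift) * w
    ty = rng.uniform(-policy.height_shift, policy.height_shift) * h
    flip = policy.horizontal_flip and rng.random() < 0.5

    # output->input map in (row, col) coordinates
    c, s = math.cos(angle), math.sin(angle)
    rot = np.array([[c, -s], [s, c]])
    shr = np.array([[1.0, shear], [0.0, 1.0]])
    mat = (rot @ shr) / zoom
    if flip:
        mat = mat @ np.array([[1.0, 0.0], [0.0, -1.0]])
    centre = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    offset = centre - mat @ centre + np.array([ty, tx])
    return mat, offset


def _transform_one(img: np.ndarray, policy: AugmentPolicy, rng: np.random.Generator) -> np.ndarray:
    mat, offset = _random_affine(policy, img.shape[:2], rng)
    out = np.empty_like(img)
    for ch in range(img.shape[2]):
        ndimage.affine_transform(
            img[:, :, ch], mat, offset=offset, output=out[:, :, ch],
            order=1, mode="nearest",
        )
    return out


def random_transform_stream(
    images: np.ndarray,
    labels: np.ndarray,
    policy: AugmentPolicy,
    batch_size: int,
    epochs: int = 1,
    shuffle: bool = False,
):
    """Yield per-epoch batches of randomly transformed samples.

    Each epoch yields ceil(n / batch_size) batches covering exactly n
    samples — the same count as the input, with every sample transformed
    afresh.  With an identity policy the yielded images equal the inputs.
    Seeded by ``policy.seed``: the same policy yields the same batches.
    """
    if batch_size < 1:
        raise ConfigurationError(f"batch_size must be >= 1, got {batch_size}")
    images = np.asarray(images)
    labels = np.asarray(labels)
    if len(images) != len(labels):
        raise ValueError(f"{len(images)} images vs {len(labels)} labels")
    n = len(images)
    rng = np.random.default_rng(policy.seed)
    identity = policy.is_identity
    for _ in range(epochs):
        order = rng.permutation(n) if shuffle else np.arange(n)
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            if identity:
                yield images[idx], labels[idx]
            else:
                batch = np.stack([_transform_one(images[i], policy, rng) for i in idx])
                yield batch, labels[idx]


def batches_per_epoch(n: int, batch_size: int) -> int:
    return math.ceil(n / batch_size)


@dataclass(frozen=True)
class SplitIndex:
    """Deterministic stratified train/test partition by image_id."""

    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    fraction: float
    seed: int

    def save(self, path) -> None:
        frame = pd.DataFrame(
            {
                "image_id": list(self.train_ids) + list(self.test_ids),
                "partition": ["train"] * len(self.train_ids) + ["test"] * len(self.test_ids),
            }
        )
        frame.attrs["fraction"] = self.fraction
        frame.to_csv(path, index=False)

    @classmethod
    def load(cls, path, fraction: float = 0.8, seed: int = 42) -> "SplitIndex":
        frame = pd.read_csv(path)
        return cls(
            train_ids=tuple(frame.loc[frame["partition"] == "train", "image_id"]),
            test_ids=tuple(frame.loc[frame["partition"] == "test", "image_id"]),
            fraction=fraction,
            seed=seed,
        )


def stratified_split(ids, labels, fraction: float = 0.8, seed: int = 42) -> SplitIndex:
    """Per-class shuffle-then-split; train size = round(fraction * n) per class.

    For class-balanced inputs whose per-class count times fraction is
    integral, proportions are preserved exactly (100/class at 0.8 gives
    80/20 per class).
    """
    if not 0.0 < fraction < 1.0:
        raise ConfigurationError(f"fraction must be in (0, 1), got {fraction}")
    ids = list(ids)
    labels = list(labels)
    if len(ids) != len(labels):
        raise ValueError(f"{len(ids)} ids vs {len(labels)} labels")
    rng = np.random.default_rng(seed)
    train: list[str] = []
    test: list[str] = []
    for cls in sorted(set(labels)):
        members = [i for i, lab in zip(ids, labels) if lab == cls]
        n = len(members)
        n_train = int(round(fraction * n))
        if n < 2 and (n_train == 0 or n_train == n):
            warnings.warn(
                f"class {cls!r} has {n} member(s); one side of the split is empty",
                stacklevel=2,
            )
        perm = rng.permutation(n)
        train.extend(members[i] for i in perm[:n_train])
        test.extend(members[i] for i in perm[n_train:])
    return SplitIndex(tuple(train), tuple(test), fraction, seed)
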