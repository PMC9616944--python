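"""Synthetic dermoscopy-like image generator for the seven lesion classes.

Each class gets a distinct parametric signature along the three axes the
downstream global descriptors measure:

* colour   — the lesion blob's base hue/saturation/value (colour histogram),
* shape    — the blob's eccentricity and relative area (Hu moments),
* texture  — an additive oriented sinusoid of class-specific frequency plus
             speckle noise inside the blob (Haralick statistics).

Backgrounds are a fixed beige skin tone with mild Gaussian noise, mimicking
dermoscopic framing where the lesion is cropped and centred.  The images are
synthetic stand-ins for real dermoscopy: they make the pipeline testable and
learnable, not photorealistic.

Determinism contract: identical :class:`SynthConfig` (including seed) yields
byte-identical PNG files.  Every image draws from its own child generator
seeded by (seed, class index, image index), so the set of files produced
does not depend on generation order.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.color import hsv2rgb

from .dataset import CLASS_CODES, METADATA_COLUMNS, DatasetManifest, order_by_class
from .errors import ConfigurationError


@dataclass(frozen=True)
class ClassSignature:
    """Parametric appearance of one lesion class."""

    hue: float          # base hue of the lesion blob, in [0, 1)
    saturation: float   # blob saturation
    value: float        # blob brightness
    axis_ratio: float   # minor/major semi-axis ratio (1 = circular)
    area: float         # blob area as a fraction of the image
    frequency: float    # texture cycles across the blob diameter
    tex_amp: float      # amplitude of the oriented sinusoid, intensity units
    speckle_sd: float   # SD of additive speckle noise inside the blob


# Signatures are spaced widely in hue/shape/frequency so that the colour
# histogram, Hu and Haralick descriptors are each discriminative on their own.
DEFAULT_SIGNATURES: dict[str, ClassSignature] = {
    "akiec": ClassSignature(0.98, 0.55, 0.55, 0.95, 0.16, 2.0, 10.0, 4.0),
    "bcc":   ClassSignature(0.07, 0.65, 0.70, 0.75, 0.22, 5.0, 18.0, 8.0),
    "bkl":   ClassSignature(0.12, 0.80, 0.40, 0.55, 0.30, 9.0, 26.0, 12.0),
    "df":    ClassSignature(0.33, 0.45, 0.45, 0.40, 0.10, 13.0, 22.0, 20.0),
    "mel":   ClassSignature(0.75, 0.50, 0.25, 0.65, 0.38, 17.0, 30.0, 28.0),
    "nv":    ClassSignature(0.55, 0.60, 0.60, 0.90, 0.26, 3.5, 14.0, 16.0),
    "vasc":  ClassSignature(0.88, 0.85, 0.75, 0.85, 0.14, 7.0, 20.0, 36.0),
}

_BACKGROUND_RGB = np.array([205.0, 170.0, 148.0])  # beige skin tone
_DX_TYPES = (("histo", 0.54), ("follow_up", 0.27), ("consensus", 0.15), ("confocal", 0.04))
_SEXES = (("male", 0.52), ("female", 0.46), ("unknown", 0.02))
_LOCALIZATIONS = (
    "back", "lower extremity", "trunk", "upper extremity",
    "abdomen", "face", "chest", "foot", "neck", "scalp",
)


@dataclass(frozen=True)
class SynthConfig:
    """Configuration of a synthetic seven-class dataset."""

    n_per_class: int = 100
    image_size: int = 220
    seed: int = 0
    class_names: tuple[str, ...] = CLASS_CODES
    signatures: dict[str, ClassSignature] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_SIGNATURES)
    )

    def __post_init__(self):
        if self.n_per_class < 1:
            raise ConfigurationError(f"n_per_class must be >= 1, got {self.n_per_class}")
        if self.image_size < 8:
            raise ConfigurationError(f"image_size must be >= 8, got {self.image_size}")
        names = tuple(self.class_names)
        if len(names) != 7 or len(set(names)) != 7:
            raise ConfigurationError("class_names must be 7 unique codes")
        object.__setattr__(self, "class_names", names)
        missing = set(names) - set(self.signatures)
        if missing:
            raise ConfigurationError(f"no signature for class(es): {sorted(missing)}")


def _render_image(sig: ClassSignature, size: int, rng: np.random.Generator) -> np.ndarray:
    """Render one lesion image as uint8 RGB."""
    img = _BACKGROUND_RGB[None, None, :] + rng.normal(0.0, 4.0, (size, size, 3))

    # elliptical lesion mask, jittered centre / axes / orientation
    area = sig.area * (1.0 + rng.uniform(-0.15, 0.15))
    a = np.sqrt(area * size * size / (np.pi * sig.axis_ratio))  # major semi-axis
    b = a * sig.axis_ratio
    cx, cy = (size / 2) * (1.0 + rng.uniform(-0.08, 0.08, 2))
    theta = rng.uniform(0.0, np.pi)
    yy, xx = np.mgrid[0:size, 0:size]
    xr = (xx - cx) * np.cos(theta) + (yy - cy) * np.sin(theta)
    yr = -(xx - cx) * np.sin(theta) + (yy - cy) * np.cos(theta)
    mask = (xr / a) ** 2 + (yr / b) ** 2 <= 1.0

    hsv = np.array(
        [
            (sig.hue + rng.normal(0.0, 0.01)) % 1.0,
            np.clip(sig.saturation + rng.normal(0.0, 0.04), 0.05, 1.0),
            np.clip(sig.value + rng.normal(0.0, 0.04), 0.05, 1.0),
        ]
    )
    lesion_rgb = hsv2rgb(hsv[None, None, :])[0, 0] * 255.0

    # oriented sinusoid across the blob diameter + speckle, texture signature
    phi = rng.uniform(0.0, 2 * np.pi)
    tex_dir = rng.uniform(0.0, np.pi)
    proj = (xx - cx) * np.cos(tex_dir) + (yy - cy) * np.sin(tex_dir)
    sinusoid = sig.tex_amp * np.sin(2 * np.pi * sig.frequency * proj / (2 * a) + phi)
    speckle = rng.normal(0.0, sig.speckle_sd, (size, size))

    lesion = lesion_rgb[None, None, :] + (sinusoid + speckle)[:, :, None]
    img[mask] = lesion[mask]
    return np.clip(img, 0.0, 255.0).round().astype(np.uint8)


def generate_dataset(config: SynthConfig, out_dir: str | Path) -> DatasetManifest:
    """Write a synthetic dataset (per-class PNG folders + metadata CSV).

    Layout mirrors a class-sorted HAM10000 dump::

        out_dir/metadata.csv
        out_dir/<dx>/<image_id>.png

    Returns the manifest produced by re-reading the written artifacts, so
    the returned object is guaranteed consistent with the on-disk state.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory not writable: {out_dir}") from exc

    rows = []
    for ci, cls in enumerate(config.class_names):
        cls_dir = out_dir / cls
        cls_dir.mkdir(exist_ok=True)
        sig = config.signatures[cls]
        for i in range(config.n_per_class):
            rng = np.random.default_rng([config.seed, ci, i])
            pixels = _render_image(sig, config.image_size, rng)
            image_id = f"SYN_{cls}_{i:04d}"
            Image.fromarray(pixels).save(cls_dir / f"{image_id}.png")
            age = float(np.clip(5 * round(rng.normal(50.0, 15.0) / 5), 5, 85))
            rows.append(
                {
                    "lesion_id": f"SYNL_{cls}_{i // 2:04d}",
                    "image_id": image_id,
                    "dx": cls,
                    "dx_type": _draw(_DX_TYPES, rng),
                    "age": age,
                    "sex": _draw(_SEXES, rng),
                    "localization": _LOCALIZATIONS[int(rng.integers(len(_LOCALIZATIONS)))],
                }
            )

    metadata = pd.DataFrame(rows, columns=list(METADATA_COLUMNS))
    metadata.to_csv(out_dir / "metadata.csv", index=False)
    return order_by_class(metadata, out_dir)


def _draw(table: tuple[tuple[str, float], ...], rng: np.random.Generator) -> str:
    names, probs = zip(*table)
    p = np.asarray(probs) / np.sum(probs)
    return names[int(rng.choice(len(names), p=p))]
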