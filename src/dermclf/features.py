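"""Global image descriptors and the HDF5 feature store.

Three descriptors quantify a lesion image as a whole, with no interest
points or segmentation mask:

* colour  — a flattened 3-D joint colour histogram (default HSV, 8 bins
  per channel, L1-normalised),
* shape   — the seven Hu invariant moments of the grayscale image
  (translation/scale/rotation invariant; the 7th flips sign under
  reflection), log-magnitude transformed by default,
* texture — the 13 classical Haralick statistics of a symmetric,
  normalised gray-level co-occurrence matrix, averaged over four
  displacement angles.

Concatenated in that order they form a single global feature vector
(default 8**3 + 7 + 13 = 532 values) persisted to HDF5 with its label.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import h5py
import numpy as np
from skimage.color import rgb2hsv
from skimage.feature import graycomatrix
from skimage.measure import moments_central, moments_hu, moments_normalized

from .dataset import LesionImage
from .errors import ConfigurationError, FormatError, SchemaError

_LUMA = np.array([0.299, 0.587, 0.114])  # ITU-R BT.601
_HU_EPS = 1e-30
_LOG_EPS = 1e-12  # guard inside GLCM entropy terms


@dataclass(frozen=True)
class DescriptorConfig:
    """Settings of the three global descriptors.

    Defaults follow canonical practice: an HSV joint histogram with 8 bins
    per channel, a GLCM at distance 1 over the four standard angles with 8
    quantisation levels, and log-magnitude Hu moments (raw invariants span
    ~1e-20..1e-1, unusable by distance-based learners).
    """

    hist_bins_per_channel: int = 8
    hist_color_space: str = "HSV"
    glcm_levels: int = 8
    glcm_distances: tuple[int, ...] = (1,)
    glcm_angles: tuple[float, ...] = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)
    hu_log_transform: bool = True

    def __post_init__(self):
        if self.hist_bins_per_channel < 1:
            raise ConfigurationError("hist_bins_per_channel must be >= 1")
        if self.glcm_levels < 2:
            raise ConfigurationError("glcm_levels must be >= 2")
        if self.hist_color_space not in ("HSV", "RGB"):
            raise ConfigurationError(f"unknown color space {self.hist_color_space!r}")
        object.__setattr__(self, "glcm_distances", tuple(self.glcm_distances))
        object.__setattr__(self, "glcm_angles", tuple(float(a) for a in self.glcm_angles))

    @property
    def feature_length(self) -> int:
        return self.hist_bins_per_channel ** 3 + 7 + 13

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "DescriptorConfig":
        d = json.loads(text)
        d["glcm_distances"] = tuple(d["glcm_distances"])
        d["glcm_angles"] = tuple(d["glcm_angles"])
        return cls(**d)


@dataclass(frozen=True)
class FeatureVector:
    """One image's concatenated global descriptor plus its label."""

    image_id: str
    values: np.ndarray
    label: str


def to_grayscale(img: LesionImage | np.ndarray) -> np.ndarray:
    """BT.601 luma in float, range [0, 255]."""
    pixels = img.pixels if isinstance(img, LesionImage) else np.asarray(img)
    return pixels.astype(np.float64) @ _LUMA


def color_histogram(img: LesionImage, cfg: DescriptorConfig | None = None) -> np.ndarray:
    """Flattened 3-D joint colour histogram, L1-normalised to sum 1."""
    cfg = cfg or DescriptorConfig()
    pixels = img.pixels
    if pixels.size == 0:
        raise ValueError("empty image")
    if cfg.hist_color_space == "HSV":
        data = rgb2hsv(pixels)
    else:
        data = pixels.astype(np.float64) / 255.0
    b = cfg.hist_bins_per_channel
    hist, _ = np.histogramdd(
        data.reshape(-1, 3), bins=(b, b, b), range=[(0.0, 1.0)] * 3
    )
    return (hist / hist.sum()).ravel()


def hu_moments(img: LesionImage | np.ndarray, cfg: DescriptorConfig | None = None) -> np.ndarray:
    """Seven Hu invariants of the grayscale image.

    With ``hu_log_transform`` each invariant h maps to
    -sign(h) * log10(|h| + 1e-30), compressing the huge dynamic range while
    preserving sign information.  An all-zero image has no defined moments;
    by convention it yields the zero vector rather than an exception.
    """
    cfg = cfg or DescriptorConfig()
    gray = to_grayscale(img)
    if gray.sum() == 0.0:
        hu = np.zeros(7)
    else:
        mu = moments_central(gray)
        hu = moments_hu(moments_normalized(mu))
    if cfg.hu_log_transform:
        hu = -np.sign(hu) * np.log10(np.abs(hu) + _HU_EPS)
    return hu


def quantize_gray(gray: np.ndarray, levels: int) -> np.ndarray:
    """Uniformly quantise [0, 255] intensities to ``levels`` integer levels."""
    return np.minimum((gray * levels / 256.0).astype(np.int64), levels - 1)


def _haralick_13(p: np.ndarray) -> np.ndarray:
    """The 13 Haralick statistics of one normalised symmetric GLCM.

    Entropies use log base 2.  Sum variance is computed about the sum
    average.  Correlation and the information measures degenerate on a
    constant image (zero marginal variance / entropy); they are reported
    as 0 by convention.
    """
    L = p.shape[0]
    i = np.arange(L)
    ii, jj = np.meshgrid(i, i, indexing="ij")

    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = (i * px).sum()
    mu_y = (i * py).sum()
    sd_x = np.sqrt(((i - mu_x) ** 2 * px).sum())
    sd_y = np.sqrt(((i - mu_y) ** 2 * py).sum())

    # distributions of i+j (range 0..2L-2) and |i-j| (range 0..L-1)
    p_sum = np.zeros(2 * L - 1)
    np.add.at(p_sum, (ii + jj).ravel(), p.ravel())
    p_diff = np.zeros(L)
    np.add.at(p_diff, np.abs(ii - jj).ravel(), p.ravel())
    k_sum = np.arange(2 * L - 1)
    k_diff = np.arange(L)

    asm = (p ** 2).sum()
    contrast = (k_diff ** 2 * p_diff).sum()
    if sd_x > 0 and sd_y > 0:
        correlation = ((ii * jj * p).sum() - mu_x * mu_y) / (sd_x * sd_y)
    else:
        correlation = 0.0
    variance = ((ii - mu_x) ** 2 * p).sum()  # sum of squares about the marginal mean
    idm = (p / (1.0 + (ii - jj) ** 2)).sum()
    sum_avg = (k_sum * p_sum).sum()
    sum_var = ((k_sum - sum_avg) ** 2 * p_sum).sum()
    sum_entropy = -(p_sum * np.log2(p_sum + _LOG_EPS)).sum()
    entropy = -(p * np.log2(p + _LOG_EPS)).sum()
    diff_var = ((k_diff - (k_diff * p_diff).sum()) ** 2 * p_diff).sum()
    diff_entropy = -(p_diff * np.log2(p_diff + _LOG_EPS)).sum()

    hx = -(px * np.log2(px + _LOG_EPS)).sum()
    hy = -(py * np.log2(py + _LOG_EPS)).sum()
    pxpy = np.outer(px, py)
    hxy1 = -(p * np.log2(pxpy + _LOG_EPS)).sum()
    hxy2 = -(pxpy * np.log2(pxpy + _LOG_EPS)).sum()
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    imc2 = np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy))))

    return np.array(
        [asm, contrast, correlation, variance, idm, sum_avg, sum_var,
         sum_entropy, entropy, diff_var, diff_entropy, imc1, imc2]
    )


def haralick(img: LesionImage | np.ndarray, cfg: DescriptorConfig | None = None) -> np.ndarray:
    """13 Haralick texture statistics averaged over the configured angles.

    The grayscale image is uniformly quantised to ``glcm_levels``; each
    (distance, angle) pair yields a symmetric normalised GLCM whose
    statistics are averaged over all pairs.
    """
    cfg = cfg or DescriptorConfig()
    gray = to_grayscale(img)
    q = quantize_gray(gray, cfg.glcm_levels)
    glcm = graycomatrix(
        q.astype(np.uint8),
        distances=list(cfg.glcm_distances),
        angles=list(cfg.glcm_angles),
        levels=cfg.glcm_levels,
        symmetric=True,
        normed=True,
    )
    stats = [
        _haralick_13(glcm[:, :, d, a])
        for d in range(glcm.shape[2])
        for a in range(glcm.shape[3])
    ]
    return np.mean(stats, axis=0)


def extract_global(img: LesionImage, cfg: DescriptorConfig | None = None) -> FeatureVector:
    """Concatenate histogram ‖ Hu ‖ Haralick into one global descriptor."""
    cfg = cfg or DescriptorConfig()
    values = np.concatenate([color_histogram(img, cfg), hu_moments(img, cfg), haralick(img, cfg)])
    assert values.shape == (cfg.feature_length,)
    return FeatureVector(image_id=img.image_id, values=values, label=img.label)


def extract_dataset(images, cfg: DescriptorConfig | None = None) -> list[FeatureVector]:
    cfg = cfg or DescriptorConfig()
    return [extract_global(im, cfg) for im in images]


def store_features(vectors: list[FeatureVector], path, cfg: DescriptorConfig | None = None) -> None:
    """Persist labelled feature vectors to HDF5.

    Layout: datasets ``features`` (n x d float64), ``labels`` (n strings),
    ``image_ids`` (n strings); attribute ``descriptor_config`` holds the
    JSON-serialised :class:`DescriptorConfig` when provided.
    """
    if not vectors:
        raise SchemaError("cannot store an empty feature list")
    lengths = {len(v.values) for v in vectors}
    if len(lengths) != 1:
        raise SchemaError(f"inconsistent vector lengths: {sorted(lengths)}")
    matrix = np.stack([np.asarray(v.values, dtype=np.float64) for v in vectors])
    str_dtype = h5py.string_dtype(encoding="utf-8")
    with h5py.File(path, "w") as f:
        f.create_dataset("features", data=matrix)
        f.create_dataset("labels", data=[v.label for v in vectors], dtype=str_dtype)
        f.create_dataset("image_ids", data=[v.image_id for v in vectors], dtype=str_dtype)
        if cfg is not None:
            f.attrs["descriptor_config"] = cfg.to_json()


def load_features(path) -> list[FeatureVector]:
    """Exact inverse of :func:`store_features`."""
    with h5py.File(path, "r") as f:
        for name in ("features", "labels", "image_ids"):
            if name not in f:
                raise FormatError(f"feature store {path} lacks dataset {name!r}")
        matrix = f["features"][()]
        labels = [s.decode() if isinstance(s, bytes) else s for s in f["labels"][()]]
        ids = [s.decode() if isinstance(s, bytes) else s for s in f["image_ids"][()]]
    return [
        FeatureVector(image_id=i, values=row, label=lab)
        for i, row, lab in zip(ids, matrix, labels)
    ]
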