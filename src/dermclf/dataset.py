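"""Metadata-driven dataset ordering and per-class subset selection.

The seven diagnosis codes follow the HAM10000 convention: actinic keratoses
(akiec), basal cell carcinoma (bcc), benign keratosis-like lesions (bkl),
dermatofibroma (df), melanoma (mel), melanocytic nevi (nv) and vascular
lesions (vasc).  A dataset is a folder of RGB images plus a metadata CSV
with columns lesion_id, image_id, dx, dx_type, age, sex, localization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .errors import DanglingReferenceError, InsufficiencyError, LabelError

CLASS_CODES: tuple[str, ...] = ("akiec", "bcc", "bkl", "df", "mel", "nv", "vasc")

METADATA_COLUMNS = (
    "lesion_id",
    "image_id",
    "dx",
    "dx_type",
    "age",
    "sex",
    "localization",
)

_IMAGE_EXTENSIONS = (".png", ".jpg", ".jpeg")


@dataclass(frozen=True)
class MetadataRecord:
    """One row of the metadata table, resolved to an image file on disk."""

    lesion_id: str
    image_id: str
    dx: str
    dx_type: str
    age: float | None
    sex: str
    localization: str
    path: Path | None = None


@dataclass(frozen=True)
class LesionImage:
    """An RGB lesion image with its identifier and diagnosis label."""

    image_id: str
    label: str
    pixels: np.ndarray  # H x W x 3 uint8

    def __post_init__(self):
        p = self.pixels
        if p.ndim != 3 or p.shape[2] != 3:
            raise ValueError(f"pixels must be HxWx3, got shape {p.shape}")
        if p.dtype != np.uint8:
            raise ValueError(f"pixels must be uint8, got {p.dtype}")


@dataclass
class DatasetManifest:
    """Class-ordered list of records plus per-class counts."""

    root: Path
    records: list[MetadataRecord] = field(default_factory=list)

    @property
    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CLASS_CODES}
        for r in self.records:
            counts[r.dx] += 1
        return counts

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "lesion_id": r.lesion_id,
                    "image_id": r.image_id,
                    "dx": r.dx,
                    "dx_type": r.dx_type,
                    "age": r.age,
                    "sex": r.sex,
                    "localization": r.localization,
                }
                for r in self.records
            ],
            columns=list(METADATA_COLUMNS),
        )

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _resolve_image(image_dir: Path, dx: str, image_id: str) -> Path | None:
    for sub in (image_dir / dx, image_dir):
        for ext in _IMAGE_EXTENSIONS:
            candidate = sub / f"{image_id}{ext}"
            if candidate.is_file():
                return candidate
    return None


def order_by_class(
    metadata: pd.DataFrame | str | Path, image_dir: str | Path
) -> DatasetManifest:
    """Group metadata rows by diagnosis and sort each group by image_id.

    image_id and dx are the load-bearing columns; every referenced image
    must resolve to a file either in a per-class subfolder or flat in
    ``image_dir``.  Unknown dx codes and dangling references are hard
    errors (silently dropping rows would skew the class balance).
    """
    if not isinstance(metadata, pd.DataFrame):
        metadata = pd.read_csv(metadata)
    image_dir = Path(image_dir)

    missing_cols = {"image_id", "dx"} - set(metadata.columns)
    if missing_cols:
        raise LabelError(f"metadata lacks required columns: {sorted(missing_cols)}")

    unknown = sorted(set(metadata["dx"]) - set(CLASS_CODES))
    if unknown:
        raise LabelError(f"unknown dx code(s): {unknown}")

    records: list[MetadataRecord] = []
    dangling: list[str] = []
    for row in metadata.itertuples(index=False):
        path = _resolve_image(image_dir, row.dx, row.image_id)
        if path is None:
            dangling.append(row.image_id)
            continue
        age = getattr(row, "age", None)
        records.append(
            MetadataRecord(
                lesion_id=str(getattr(row, "lesion_id", "")),
                image_id=str(row.image_id),
                dx=str(row.dx),
                dx_type=str(getattr(row, "dx_type", "")),
                age=None if age is None or pd.isna(age) else float(age),
                sex=str(getattr(row, "sex", "")),
                localization=str(getattr(row, "localization", "")),
                path=path,
            )
        )
    if dangling:
        raise DanglingReferenceError(dangling)

    records.sort(key=lambda r: (CLASS_CODES.index(r.dx), r.image_id))
    return DatasetManifest(root=image_dir, records=records)


def select_subset(manifest: DatasetManifest, n_per_class: int) -> DatasetManifest:
    """Keep the lexicographically first ``n_per_class`` images of each class.

    Deterministic by construction: the manifest is already class-grouped and
    id-sorted, so re-running always selects the same files.
    """
    if n_per_class < 1:
        raise InsufficiencyError(f"n_per_class must be >= 1, got {n_per_class}")
    counts = manifest.class_counts
    short = {c: n for c, n in counts.items() if 0 < n < n_per_class}
    # classes entirely absent from the manifest are also insufficient
    short.update({c: 0 for c, n in counts.items() if n == 0})
    if short:
        detail = ", ".join(f"{c} has {n}" for c, n in sorted(short.items()))
        raise InsufficiencyError(
            f"need {n_per_class} images per class but {detail}"
        )
    kept: list[MetadataRecord] = []
    seen = {c: 0 for c in CLASS_CODES}
    for r in manifest.records:
        if seen[r.dx] < n_per_class:
            kept.append(r)
            seen[r.dx] += 1
    return DatasetManifest(root=manifest.root, records=kept)


def load_image(record: MetadataRecord) -> LesionImage:
    with Image.open(record.path) as im:
        pixels = np.asarray(im.convert("RGB"), dtype=np.uint8)
    return LesionImage(image_id=record.image_id, label=record.dx, pixels=pixels)


def load_images(manifest: DatasetManifest) -> list[LesionImage]:
    """Load every image in manifest order (class-grouped, id-sorted)."""
    return [load_image(r) for r in manifest.records]
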