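"""Image, manifest and feature-table I/O.

All downstream geometry assumes the right-eye (OD) frame, in which the
temporal side is on the LEFT of the image and natural venous drainage in
the upper hemifield runs toward the upper left.  Left eyes (OS) are
mirrored horizontally into that frame on ingestion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from PIL import Image

from .config import DEFAULT_SCALE_MM_PER_PX

logger = logging.getLogger(__name__)

LABELS = ("symmetric", "asymmetric")
LATERALITIES = ("OD", "OS")

_REQUIRED_MANIFEST_COLUMNS = ("eye_id", "image_path", "label", "laterality")
_RATER_COLUMNS = ("rater1", "rater2", "rater3")
_DEMOGRAPHIC_COLUMNS = ("age", "va", "refraction", "axial_length", "cct")


@dataclass(frozen=True)
class EnFaceImage:
    """A square grayscale en-face slab image of Haller's layer.

    ``pixels`` holds intensities in [0, 255] (float), vessels DARK on a
    brighter background.  ``scale_mm_per_px`` converts pixel measures to mm.
    """

    pixels: np.ndarray
    laterality: str
    scale_mm_per_px: float = DEFAULT_SCALE_MM_PER_PX
    eye_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError(f"expected a 2-D image, got shape {px.shape}")
        h, w = px.shape
        if h != w:
            raise ValueError(f"non-square image: {h} x {w}")
        if h < 64:
            raise ValueError(f"image too small: {h} px (minimum 64)")
        if self.laterality not in LATERALITIES:
            raise ValueError(f"laterality must be OD or OS, got {self.laterality!r}")
        if self.scale_mm_per_px <= 0:
            raise ValueError("scale_mm_per_px must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class ManifestRecord:
    eye_id: str
    image_path: str
    label: str
    laterality: str
    rater_labels: Optional[tuple[str, str, str]] = None
    demographics: dict = field(default_factory=dict)


@dataclass(frozen=True)
class DatasetManifest:
    records: tuple[ManifestRecord, ...]

    def __post_init__(self) -> None:
        ids = [r.eye_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate eye_id(s): {dupes}")
        for r in self.records:
            if r.label not in LABELS:
                raise ValueError(f"unknown label {r.label!r} for eye {r.eye_id}")
            if r.laterality not in LATERALITIES:
                raise ValueError(
                    f"unknown laterality {r.laterality!r} for eye {r.eye_id}"
                )
            if r.rater_labels is not None:
                if len(r.rater_labels) != 3:
                    raise ValueError("rater_labels must have exactly 3 entries")
                for lab in r.rater_labels:
                    if lab not in LABELS:
                        raise ValueError(f"unknown rater label {lab!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.records]


def read_image(
    path: str | Path,
    laterality: str,
    scale_mm_per_px: float = DEFAULT_SCALE_MM_PER_PX,
    eye_id: str = "",
) -> EnFaceImage:
    """Load a PNG/BMP/TIFF en-face image as a grayscale :class:`EnFaceImage`.

    Multi-channel rasters are averaged to gray; intensities are rescaled
    to span [0, 255] only when the source is not already 8-bit.
    """
    path = Path(path)
    with Image.open(path) as im:
        arr = np.asarray(im)
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=2)
    arr = arr.astype(float)
    if arr.max() > 255.0:  # e.g. 16-bit TIFF: rescale into the 8-bit range
        lo, hi = arr.min(), arr.max()
        arr = (arr - lo) / (hi - lo) * 255.0
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError(f"non-square image {path.name}: {arr.shape[0]} x {arr.shape[1]}")
    return EnFaceImage(arr, laterality, scale_mm_per_px, eye_id or path.stem)


def normalize_laterality(img: EnFaceImage, strict_od: bool = False) -> EnFaceImage:
    """Return the image in the right-eye (OD) frame.

    OD images pass through unchanged.  OS images are mirrored left-right
    (temporal side moves to the left column) and relabeled OD, so the
    mapping is idempotent.
    """
    if img.laterality == "OD":
        return img
    if strict_od:
        raise ValueError(f"left eye (OS) rejected in strict OD mode: {img.eye_id!r}")
    return replace(img, pixels=img.pixels[:, ::-1].copy(), laterality="OD")


def read_manifest(path: str | Path) -> DatasetManifest:
    """Read a dataset manifest CSV.

    Required columns: eye_id, image_path, label, laterality.  Optional:
    rater1..rater3 (three independent rater labels) and demographics
    (age, va, refraction, axial_length, cct).
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in _REQUIRED_MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing required column(s): {missing}")
    has_raters = all(c in df.columns for c in _RATER_COLUMNS)
    records = []
    for _, row in df.iterrows():
        raters = None
        if has_raters and not any(pd.isna(row[c]) for c in _RATER_COLUMNS):
            raters = tuple(str(row[c]) for c in _RATER_COLUMNS)
        demo = {
            c: float(row[c])
            for c in _DEMOGRAPHIC_COLUMNS
            if c in df.columns and not pd.isna(row[c])
        }
        records.append(
            ManifestRecord(
                eye_id=str(row["eye_id"]),
                image_path=str(row["image_path"]),
                label=str(row["label"]),
                laterality=str(row["laterality"]),
                rater_labels=raters,
                demographics=demo,
            )
        )
    return DatasetManifest(tuple(records))


def write_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    rows = []
    for r in manifest:
        row = {
            "eye_id": r.eye_id,
            "image_path": r.image_path,
            "label": r.label,
            "laterality": r.laterality,
        }
        if r.rater_labels is not None:
            row.update(dict(zip(_RATER_COLUMNS, r.rater_labels)))
        row.update(r.demographics)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


_NAN_SENTINEL = -999.0


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a feature table (eye_id index, 28 feature columns, label).

    Values round-trip at 10 significant digits.  NaNs are replaced by a
    sentinel (-999) with a logged warning.
    """
    from .features import feature_columns

    out = table.copy()
    cols = feature_columns()
    missing = [c for c in cols if c not in out.columns]
    if missing:
        raise ValueError(f"feature table missing column(s): {missing[:3]}...")
    if out[cols].isna().any().any():
        bad = out.index[out[cols].isna().any(axis=1)].tolist()
        logger.warning("NaN features for eyes %s written as sentinel %s", bad, _NAN_SENTINEL)
        out[cols] = out[cols].fillna(_NAN_SENTINEL)
    ordered = ["eye_id"] + cols + (["label"] if "label" in out.columns else [])
    if "eye_id" not in out.columns:
        out = out.reset_index().rename(columns={"index": "eye_id"})
    out[ordered].to_csv(path, index=False, float_format="%.10g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    from .features import feature_columns

    df = pd.read_csv(path)
    missing = [c for c in feature_columns() if c not in df.columns]
    if missing:
        raise ValueError(f"feature table missing column(s): {missing[:3]}...")
    return df
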