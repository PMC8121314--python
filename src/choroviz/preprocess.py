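"""Binarization, denoising, thinning and region-wise vessel metrics.

The en-face image shows vessels dark on a brighter background; the binary
mask produced here has vessels as foreground (True).  The centerline is
obtained by Zhang-Suen iterative thinning, after which vessel area, length
and mean diameter are measured per region (upper/lower hemifield split at
the horizontal watershed line, temporal/nasal split at the vertical
midline; temporal = left half in the right-eye frame).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_holes, remove_small_objects

from .core_io import EnFaceImage

logger = logging.getLogger(__name__)

REGIONS = ("upper", "lower", "temporal", "nasal", "whole")


@dataclass(frozen=True)
class RegionMetrics:
    """Basic vessel metrics of one image region, in physical units."""

    region: str
    vessel_area: float  # mm^2
    vessel_length: float  # mm
    mean_diameter: float  # mm


def binarize(img: EnFaceImage) -> np.ndarray:
    """Threshold an en-face image into a vessel mask (vessels = True).

    The threshold maximizes the between-class variance of the intensity
    histogram (Otsu's discriminant criterion); pixels at or below the
    threshold — the dark vessels — become foreground.
    """
    px = img.pixels
    if np.ptp(px) == 0:
        raise ValueError("degenerate histogram: constant image cannot be binarized")
    thr = threshold_otsu(px.astype(np.uint8), nbins=256)
    return px <= thr


def denoise(mask: np.ndarray, min_component_px: int) -> np.ndarray:
    """Remove speckle and fill pinholes smaller than ``min_component_px``.

    Both foreground components and background holes are treated
    8-connected.  May return an empty mask (logged).
    """
    mask = np.asarray(mask, bool)
    # max_size removes components <= value; keep strictly-smaller-than semantics
    out = remove_small_objects(mask, max_size=min_component_px - 1, connectivity=2)
    out = remove_small_holes(out, max_size=min_component_px - 1, connectivity=2)
    if mask.any() and not out.any():
        logger.warning("denoising removed all foreground (min_component_px=%d)", min_component_px)
    return out


# Zhang-Suen neighborhood, clockwise from north:
#   P9 P2 P3
#   P8 P1 P4
#   P7 P6 P5
_NEIGHBOR_OFFSETS = [
    (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1),
]  # P2..P9


def _zs_subiteration(img: np.ndarray, step: int) -> np.ndarray:
    """One parallel Zhang-Suen sub-iteration; returns the deletion mask."""
    p = [
        np.roll(np.roll(img, -dr, axis=0), -dc, axis=1)
        for dr, dc in _NEIGHBOR_OFFSETS
    ]
    # wrapped-around borders must read as background
    for k, (dr, dc) in enumerate(_NEIGHBOR_OFFSETS):
        if dr == -1:
            p[k][0, :] = 0
        elif dr == 1:
            p[k][-1, :] = 0
        if dc == -1:
            p[k][:, 0] = 0
        elif dc == 1:
            p[k][:, -1] = 0
    b = sum(p)
    seq = p + [p[0]]
    a = sum((seq[k] == 0) & (seq[k + 1] == 1) for k in range(8))
    p2, p4, p6, p8 = p[0], p[2], p[4], p[6]
    if step == 0:
        c1 = (p2 * p4 * p6) == 0
        c2 = (p4 * p6 * p8) == 0
    else:
        c1 = (p2 * p4 * p8) == 0
        c2 = (p2 * p6 * p8) == 0
    return (img == 1) & (b >= 2) & (b <= 6) & (a == 1) & c1 & c2


def skeletonize(mask: np.ndarray) -> np.ndarray:
    """Thin a binary mask to its one-pixel-wide centerline (Zhang-Suen).

    The two sub-iterations are applied in parallel passes until a full
    iteration deletes nothing.  The skeleton is a subset of the mask and
    re-thinning is a no-op.
    """
    img = np.asarray(mask, bool).astype(np.uint8)
    while True:
        changed = False
        for step in (0, 1):
            deletion = _zs_subiteration(img, step)
            if deletion.any():
                img[deletion] = 0
                changed = True
        if not changed:
            return img.astype(bool)


def region_slices(shape: tuple[int, int], region: str) -> tuple[slice, slice]:
    """Half-image slice for a named region (half-open split at H/2, W/2)."""
    h, w = shape
    if region == "upper":
        return slice(0, h // 2), slice(None)
    if region == "lower":
        return slice(h // 2, h), slice(None)
    if region == "temporal":  # left half in the OD frame
        return slice(None), slice(0, w // 2)
    if region == "nasal":
        return slice(None), slice(w // 2, w)
    if region == "whole":
        return slice(None), slice(None)
    raise ValueError(f"unknown region {region!r}")


def region_metrics(
    mask: np.ndarray, skel: np.ndarray, region: str, scale_mm_per_px: float
) -> RegionMetrics:
    """Vessel area, length and mean diameter within one region.

    area = foreground px x scale^2; length = skeleton px x scale;
    mean diameter = area / length (0 when there is no skeleton).
    """
    if mask.shape != skel.shape:
        raise ValueError("mask and skeleton shapes differ")
    rs, cs = region_slices(mask.shape, region)
    area = float(mask[rs, cs].sum()) * scale_mm_per_px**2
    length = float(skel[rs, cs].sum()) * scale_mm_per_px
    diameter = area / length if length > 0 else 0.0
    return RegionMetrics(region, area, length, diameter)
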