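"""Ladder-pattern image: coarse caliber/length trends of the vessel mask.

Horizontal sampling lines are drawn every ``spacing`` rows; each line
pixel is set white when the majority of mask pixels in a vertical
``strip``-row window centred on the line is white.  Maximal horizontal
white runs on the lines act as vessel cross-sections: their count and
lengths summarise caliber and total length trends per region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import region_slices


@dataclass(frozen=True)
class LadderImage:
    pixels: np.ndarray  # bool, True only on line rows
    line_rows: tuple[int, ...]
    spacing: int
    strip: int


@dataclass(frozen=True)
class LadderMetrics:
    region: str
    total_length: float  # mm of white ladder pixels
    mean_diameter: float  # mm, mean horizontal run length (0 if no runs)
    n_runs: int


def to_ladder(mask: np.ndarray, spacing: int = 25, strip: int = 7) -> LadderImage:
    """Build the ladder-pattern image of a binary vessel mask.

    Line rows sit at spacing, 2*spacing, ... < H.  The majority vote uses
    the rows actually available inside the image (the strip is clipped at
    the borders, not zero-padded).
    """
    if strip % 2 == 0:
        raise ValueError("strip width must be odd")
    if spacing < strip:
        raise ValueError("spacing must be >= strip width")
    mask = np.asarray(mask, bool)
    h, w = mask.shape
    half = strip // 2
    out = np.zeros_like(mask)
    rows = tuple(range(spacing, h, spacing))
    for r in rows:
        lo, hi = max(0, r - half), min(h, r + half + 1)
        window = mask[lo:hi]
        votes = window.sum(axis=0)
        out[r] = votes * 2 > (hi - lo)  # strict majority of available rows
    return LadderImage(out, rows, spacing, strip)


def _runs_in_row(row: np.ndarray) -> list[int]:
    """Lengths of maximal True runs in a 1-D boolean row."""
    padded = np.concatenate(([0], row.astype(np.int8), [0]))
    diff = np.diff(padded)
    starts = np.nonzero(diff == 1)[0]
    ends = np.nonzero(diff == -1)[0]
    return (ends - starts).tolist()


def ladder_metrics(
    lad: LadderImage, region: str, scale_mm_per_px: float
) -> LadderMetrics:
    """Total white length and mean run length within one region half."""
    rs, cs = region_slices(lad.pixels.shape, region)
    sub = lad.pixels[rs, cs]
    runs: list[int] = []
    for r in range(sub.shape[0]):
        if sub[r].any():
            runs.extend(_runs_in_row(sub[r]))
    total = float(sub.sum()) * scale_mm_per_px
    mean_d = float(np.mean(runs)) * scale_mm_per_px if runs else 0.0
    return LadderMetrics(region, total, mean_d, len(runs))
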