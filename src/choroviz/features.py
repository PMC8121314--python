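"""The 28-feature vector quantifying hemifield symmetry of the vasculature.

Feature layout (fixed order):
  1-6   vessel area (mm^2), length (mm), mean diameter (mm), upper then lower
  7-8   upper/lower ratio and difference of mean diameter
  9-10  fractions of midline-crossing segments per diagonal axis
  11-14 length-weighted natural/unnatural oblique percentages per hemifield
  15-20 derived ratios/differences of the oblique percentages
  21-24 upper/lower ladder-image differences and ratios (diameter, length)
  25-28 temporal/nasal ladder-image differences and ratios

Hemifield quantities are computed in a canonical frame: the lower
hemifield is flipped vertically and processed with exactly the same
algorithms (and the upper-hemifield drainage band) as the upper one.
This is mathematically identical to applying the mirrored lower-hemifield
band, and it guarantees that an exactly mirror-symmetric image yields
ratio features of exactly 1 and difference features of exactly 0 —
iterative thinning is not mirror-equivariant, so a whole-image pass
cannot make that guarantee.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .config import DEFAULT_CONFIG, PipelineConfig
from .core_io import EnFaceImage, normalize_laterality
from .ladder import LadderMetrics, ladder_metrics, to_ladder
from .preprocess import binarize, denoise, skeletonize
from .vessel_graph import (
    classify_segments,
    extract_segments,
    midline_crossing_ratios,
    oblique_ratios,
)

logger = logging.getLogger(__name__)

#: Stable column identifiers, in fixed order (row numbering of the table).
FEATURE_COLUMNS = (
    "vessel_area_upper_mm2",
    "vessel_length_upper_mm",
    "mean_vessel_diameter_upper_mm",
    "vessel_area_lower_mm2",
    "vessel_length_lower_mm",
    "mean_vessel_diameter_lower_mm",
    "upper_lower_ratio_mean_diameter",
    "upper_lower_diff_mean_diameter",
    "crossing_ratio_upper_temporal_to_lower_nasal",
    "crossing_ratio_upper_nasal_to_lower_temporal",
    "natural_oblique_pct_upper",
    "unnatural_oblique_pct_upper",
    "natural_oblique_pct_lower",
    "unnatural_oblique_pct_lower",
    "natural_unnatural_ratio_upper",
    "natural_unnatural_ratio_lower",
    "ratio_f15_f16",
    "diff_f15_f16",
    "upper_lower_ratio_natural",
    "upper_lower_diff_natural",
    "upper_lower_diff_mean_diameter_ladder",
    "upper_lower_diff_total_length_ladder",
    "upper_lower_ratio_mean_diameter_ladder",
    "upper_lower_ratio_total_length_ladder",
    "temporal_nasal_diff_mean_diameter_ladder",
    "temporal_nasal_diff_total_length_ladder",
    "temporal_nasal_ratio_mean_diameter_ladder",
    "temporal_nasal_ratio_total_length_ladder",
)

#: Human-readable display names, same order.
_DISPLAY_NAMES = (
    "vessel area, upper side (mm^2)",
    "vessel length, upper side (mm)",
    "mean vessel diameter, upper side (mm)",
    "vessel area, lower side (mm^2)",
    "Vessel length, lower side (mm)",
    "mean vessel diameter, lower side (mm)",
    "Upper to lower ratio of mean vessel diameter",
    "Upper to lower difference of mean vessel diameter",
    "ratio of vessels flowing from upper temporal side to lower nasal side",
    "ratio of vessels flowing from upper nasal side to lower temporal side",
    "ratio of natural oblique vessel, upper side (%)",
    "ratio of unnatural oblique vessel, upper side (%)",
    "ratio of natural oblique vessel, lower side (%)",
    "ratio of unnatural oblique vessel, lower side (%)",
    "Ratio of natural to unnatural oblique vessel, upper side",
    "Ratio of natural to unnatural oblique vessel, lower side",
    "Ratio of No.15 feature to No.16 feature",
    "Difference of No.15 feature between No.16 feature",
    "Upper to lower ratio of natural oblique vessel",
    "Upper to lower difference of natural oblique vessel",
    "Upper to lower difference of mean vessel diameter, ladder pattern image (mm)",
    "Upper to lower difference of total vessel length, ladder pattern image (mm)",
    "Upper to lower ratio of mean vessel diameter, ladder pattern image",
    "Upper to lower ratio of total vessel length, ladder pattern image",
    "Temporal to nasal difference of mean vessel diameter, ladder pattern image (mm)",
    "Temporal to nasal difference of total vessel length, ladder pattern image (mm)",
    "Temporal to nasal ratio of mean vessel diameter, ladder pattern image",
    "Temporal to nasal ratio of total vessel length, ladder pattern image",
)


def feature_names() -> list[str]:
    """The 28 human-readable feature names, in fixed table order."""
    return list(_DISPLAY_NAMES)


def feature_columns() -> list[str]:
    """The 28 machine-friendly column identifiers, same order."""
    return list(FEATURE_COLUMNS)


def _ratio(num: float, den: float, cap: float) -> float:
    """Guarded ratio: zero denominators map to the sentinel cap."""
    if den == 0.0:
        return cap
    return num / den


@dataclass(frozen=True)
class HemifieldAnalysis:
    """Per-hemifield intermediates, in the canonical (upper-frame) state."""

    area_mm2: float
    length_mm: float
    mean_diameter_mm: float
    natural_pct: float
    unnatural_pct: float
    ladder: LadderMetrics


def _analyze_hemifield(
    half_mask: np.ndarray, cfg: PipelineConfig, scale: float
) -> HemifieldAnalysis:
    """Run thinning, segmentation and ladder analysis on one hemifield.

    ``half_mask`` must already be in the canonical orientation (the lower
    hemifield flipped so its natural drainage band coincides with the
    upper one).
    """
    s = scale
    skel = skeletonize(half_mask)
    area = float(half_mask.sum()) * s * s
    length = float(skel.sum()) * s
    diameter = area / length if length > 0 else 0.0
    segments = extract_segments(skel)
    # canonical frame: every segment is classified with the upper-hemifield band
    segments = [
        seg.__class__(
            path=seg.path,
            length_px=seg.length_px,
            orientation_deg=seg.orientation_deg,
            region="upper",
        )
        for seg in segments
    ]
    segments = classify_segments(segments, cfg.min_segment_px)
    ratios = oblique_ratios(segments, regions=("upper",))
    lad = to_ladder(half_mask, cfg.ladder_spacing_px, cfg.ladder_strip_px)
    lm = ladder_metrics(lad, "whole", s)
    return HemifieldAnalysis(
        area_mm2=area,
        length_mm=length,
        mean_diameter_mm=diameter,
        natural_pct=ratios["upper_natural_pct"],
        unnatural_pct=ratios["upper_unnatural_pct"],
        ladder=lm,
    )


def compute_features(
    img: EnFaceImage, cfg: PipelineConfig = DEFAULT_CONFIG
) -> dict[str, float]:
    """Compute the 28-feature vector of one en-face image.

    The image is brought into the right-eye frame, binarized (vessels
    dark -> foreground), denoised, and analysed per hemifield in the
    canonical orientation; midline-crossing statistics and the
    temporal/nasal ladder metrics use the whole image.

    Returns a dict keyed by :data:`FEATURE_COLUMNS`, never containing
    NaN (zero-denominator ratios are capped at ``cfg.ratio_cap``).
    """
    img = normalize_laterality(img, strict_od=cfg.strict_od)
    h = img.height
    mask = denoise(binarize(img), cfg.min_component_for(h))
    if not mask.any():
        raise ValueError("no vasculature detected after binarization/denoising")

    scale = img.scale_mm_per_px  # the image's own scale governs mm units
    upper = _analyze_hemifield(mask[: h // 2], cfg, scale)
    lower = _analyze_hemifield(mask[h // 2 :][::-1], cfg, scale)

    # whole-image skeleton only for midline-crossing statistics
    whole_segments = classify_segments(
        extract_segments(skeletonize(mask)), cfg.min_segment_px
    )
    f9, f10 = midline_crossing_ratios(whole_segments, h)

    # temporal/nasal trends from the whole-image ladder
    lad = to_ladder(mask, cfg.ladder_spacing_px, cfg.ladder_strip_px)
    lm_t = ladder_metrics(lad, "temporal", scale)
    lm_n = ladder_metrics(lad, "nasal", scale)

    cap = cfg.ratio_cap
    f: dict[str, float] = {}
    f["vessel_area_upper_mm2"] = upper.area_mm2
    f["vessel_length_upper_mm"] = upper.length_mm
    f["mean_vessel_diameter_upper_mm"] = upper.mean_diameter_mm
    f["vessel_area_lower_mm2"] = lower.area_mm2
    f["vessel_length_lower_mm"] = lower.length_mm
    f["mean_vessel_diameter_lower_mm"] = lower.mean_diameter_mm
    f["upper_lower_ratio_mean_diameter"] = _ratio(
        upper.mean_diameter_mm, lower.mean_diameter_mm, cap
    )
    f["upper_lower_diff_mean_diameter"] = upper.mean_diameter_mm - lower.mean_diameter_mm
    f["crossing_ratio_upper_temporal_to_lower_nasal"] = f9
    f["crossing_ratio_upper_nasal_to_lower_temporal"] = f10
    f["natural_oblique_pct_upper"] = upper.natural_pct
    f["unnatural_oblique_pct_upper"] = upper.unnatural_pct
    f["natural_oblique_pct_lower"] = lower.natural_pct
    f["unnatural_oblique_pct_lower"] = lower.unnatural_pct
    f15 = _ratio(upper.natural_pct, upper.unnatural_pct, cap)
    f16 = _ratio(lower.natural_pct, lower.unnatural_pct, cap)
    f["natural_unnatural_ratio_upper"] = f15
    f["natural_unnatural_ratio_lower"] = f16
    f["ratio_f15_f16"] = _ratio(f15, f16, cap)
    f["diff_f15_f16"] = f15 - f16
    f["upper_lower_ratio_natural"] = _ratio(upper.natural_pct, lower.natural_pct, cap)
    f["upper_lower_diff_natural"] = upper.natural_pct - lower.natural_pct

    du, dl = upper.ladder.mean_diameter, lower.ladder.mean_diameter
    lu, ll = upper.ladder.total_length, lower.ladder.total_length
    dt, dn = lm_t.mean_diameter, lm_n.mean_diameter
    lt, ln = lm_t.total_length, lm_n.total_length
    diff = abs if cfg.abs_ladder_diff else (lambda x: x)
    f["upper_lower_diff_mean_diameter_ladder"] = diff(du - dl)
    f["upper_lower_diff_total_length_ladder"] = diff(lu - ll)
    f["upper_lower_ratio_mean_diameter_ladder"] = _ratio(du, dl, cap)
    f["upper_lower_ratio_total_length_ladder"] = _ratio(lu, ll, cap)
    f["temporal_nasal_diff_mean_diameter_ladder"] = diff(dt - dn)
    f["temporal_nasal_diff_total_length_ladder"] = diff(lt - ln)
    f["temporal_nasal_ratio_mean_diameter_ladder"] = _ratio(dt, dn, cap)
    f["temporal_nasal_ratio_total_length_ladder"] = _ratio(lt, ln, cap)

    assert set(f) == set(FEATURE_COLUMNS) and not any(np.isnan(v) for v in f.values())
    return f


def feature_vector(img: EnFaceImage, cfg: PipelineConfig = DEFAULT_CONFIG) -> np.ndarray:
    """The 28 features as a float array in fixed order."""
    f = compute_features(img, cfg)
    return np.array([f[c] for c in FEATURE_COLUMNS], dtype=float)
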