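import math

import numpy as np
import pytest
from scipy import ndimage

import choroviz as cv
from choroviz.config import PipelineConfig
from choroviz.features import FEATURE_COLUMNS, feature_names

from conftest import make_mirror_symmetric_image
from oracles import brute_ladder, naive_zhang_suen

RATIO_UL = (
    "upper_lower_ratio_mean_diameter",
    "ratio_f15_f16",
    "upper_lower_ratio_natural",
    "upper_lower_ratio_mean_diameter_ladder",
    "upper_lower_ratio_total_length_ladder",
)
DIFF_UL = (
    "upper_lower_diff_mean_diameter",
    "diff_f15_f16",
    "upper_lower_diff_natural",
    "upper_lower_diff_mean_diameter_ladder",
    "upper_lower_diff_total_length_ladder",
)


class TestFeatureNames:
    def test_twenty_eight_names(self):
        assert len(feature_names()) == 28
        assert len(FEATURE_COLUMNS) == 28

    def test_printed_names_at_fixed_rows(self):
        names = feature_names()
        assert names[0] == "vessel area, upper side (mm^2)"
        assert names[14] == "Ratio of natural to unnatural oblique vessel, upper side"


class TestSymmetryForcing:
    def test_mirror_symmetric_phantom_forces_ratios_and_differences(self, mirror_image):
        f = cv.compute_features(mirror_image)
        for c in RATIO_UL:
            assert f[c] == 1.0, c
        for c in DIFF_UL:
            assert f[c] == 0.0, c

    def test_upper_only_vessels_hit_sentinel(self):
        size = 128
        canvas = np.full((size, size), 200.0)
        from choroviz.synth import _draw_capsule

        _draw_capsule(canvas, (50.0, 30.0), (10.0, 70.0), 3.0, 70.0, 200.0)
        img = cv.EnFaceImage(np.round(canvas), "OD", 7 / 512)
        f = cv.compute_features(img)
        assert f["vessel_area_lower_mm2"] == 0.0
        assert f["upper_lower_ratio_mean_diameter"] == 100.0  # sentinel cap
        assert all(np.isfinite(v) for v in f.values())

    def test_empty_image_rejected(self):
        px = np.full((128, 128), 200.0)
        px[5, 5] = 50.0  # lone dark speck, removed by denoising
        img = cv.EnFaceImage(px, "OD")
        with pytest.raises(ValueError, match="no vasculature"):
            cv.compute_features(img)


class TestScaleEquivariance:
    def test_doubling_scale(self, mirror_image):
        f1 = cv.compute_features(mirror_image)
        doubled = cv.EnFaceImage(
            mirror_image.pixels, "OD", 2 * mirror_image.scale_mm_per_px
        )
        f2 = cv.compute_features(doubled)
        for c in FEATURE_COLUMNS:
            if "area" in c:
                assert f2[c] == pytest.approx(4 * f1[c])
            elif "mm" in c or "ladder" in c and "diff" in c:
                pass
        assert f2["vessel_length_upper_mm"] == pytest.approx(2 * f1["vessel_length_upper_mm"])
        assert f2["mean_vessel_diameter_lower_mm"] == pytest.approx(
            2 * f1["mean_vessel_diameter_lower_mm"]
        )
        for c in ("natural_oblique_pct_upper", "ratio_f15_f16",
                  "upper_lower_ratio_total_length_ladder",
                  "crossing_ratio_upper_temporal_to_lower_nasal"):
            assert f2[c] == pytest.approx(f1[c])

    def test_deterministic(self, mirror_image):
        f1 = cv.compute_features(mirror_image)
        f2 = cv.compute_features(mirror_image)
        assert f1 == f2


def _component_chord_and_length(comp_pixels):
    """Independent orientation/length: chord between the two farthest-apart
    degree-1 pixels; length = sum over 8-adjacent pixel pairs."""
    pts = sorted(map(tuple, comp_pixels))
    ptset = set(pts)
    deg = {
        p: sum(
            (p[0] + dr, p[1] + dc) in ptset
            for dr in (-1, 0, 1)
            for dc in (-1, 0, 1)
            if (dr, dc) != (0, 0)
        )
        for p in pts
    }
    ends = [p for p in pts if deg[p] == 1]
    assert len(ends) == 2, "toy strokes must skeletonize to simple paths"
    (r0, c0), (r1, c1) = ends
    theta = math.degrees(math.atan2(-(r1 - r0), c1 - c0)) % 180.0
    length = 0.0
    for i, p in enumerate(pts):
        for q in pts[i + 1 :]:
            if abs(p[0] - q[0]) <= 1 and abs(p[1] - q[1]) <= 1:
                length += math.sqrt(2) if (p[0] != q[0] and p[1] != q[1]) else 1.0
    return theta, length


def _oracle_features(mask, scale, spacing=25, strip=7, cap=100.0):
    """From-scratch computation of all 28 features for a toy mask whose
    strokes are disjoint simple curves that do not touch the midline."""
    h = mask.shape[0]
    halves = {
        "upper": mask[: h // 2],
        "lower": mask[h // 2 :][::-1],  # canonical frame
    }
    vals = {}
    side = {}
    for name, half in halves.items():
        skel = naive_zhang_suen(half)
        area = half.sum() * scale**2
        length = skel.sum() * scale
        diam = area / length if length else 0.0
        lab, n = ndimage.label(skel, structure=np.ones((3, 3)))
        nat = unnat = 0.0
        for i in range(1, n + 1):
            theta, seg_len = _component_chord_and_length(np.argwhere(lab == i))
            if 95.0 <= theta <= 175.0:
                nat += seg_len
            elif 5.0 <= theta <= 85.0:
                unnat += seg_len
        tot = nat + unnat
        nat_pct = 100.0 * nat / tot if tot else 0.0
        unnat_pct = 100.0 * unnat / tot if tot else 0.0
        lad = brute_ladder(half, spacing, strip)
        runs = []
        for r in range(lad.shape[0]):
            run = 0
            for v in list(lad[r]) + [False]:
                if v:
                    run += 1
                elif run:
                    runs.append(run)
                    run = 0
        side[name] = dict(
            area=area, length=length, diam=diam, nat=nat_pct, unnat=unnat_pct,
            lad_len=float(sum(runs)) * scale,
            lad_diam=float(np.mean(runs)) * scale if runs else 0.0,
        )

    def ratio(a, b):
        return a / b if b else cap

    u, l = side["upper"], side["lower"]
    vals["vessel_area_upper_mm2"] = u["area"]
    vals["vessel_length_upper_mm"] = u["length"]
    vals["mean_vessel_diameter_upper_mm"] = u["diam"]
    vals["vessel_area_lower_mm2"] = l["area"]
    vals["vessel_length_lower_mm"] = l["length"]
    vals["mean_vessel_diameter_lower_mm"] = l["diam"]
    vals["upper_lower_ratio_mean_diameter"] = ratio(u["diam"], l["diam"])
    vals["upper_lower_diff_mean_diameter"] = u["diam"] - l["diam"]
    vals["crossing_ratio_upper_temporal_to_lower_nasal"] = 0.0  # no midline strokes
    vals["crossing_ratio_upper_nasal_to_lower_temporal"] = 0.0
    vals["natural_oblique_pct_upper"] = u["nat"]
    vals["unnatural_oblique_pct_upper"] = u["unnat"]
    vals["natural_oblique_pct_lower"] = l["nat"]
    vals["unnatural_oblique_pct_lower"] = l["unnat"]
    f15 = ratio(u["nat"], u["unnat"])
    f16 = ratio(l["nat"], l["unnat"])
    vals["natural_unnatural_ratio_upper"] = f15
    vals["natural_unnatural_ratio_lower"] = f16
    vals["ratio_f15_f16"] = ratio(f15, f16)
    vals["diff_f15_f16"] = f15 - f16
    vals["upper_lower_ratio_natural"] = ratio(u["nat"], l["nat"])
    vals["upper_lower_diff_natural"] = u["nat"] - l["nat"]
    vals["upper_lower_diff_mean_diameter_ladder"] = u["lad_diam"] - l["lad_diam"]
    vals["upper_lower_diff_total_length_ladder"] = u["lad_len"] - l["lad_len"]
    vals["upper_lower_ratio_mean_diameter_ladder"] = ratio(u["lad_diam"], l["lad_diam"])
    vals["upper_lower_ratio_total_length_ladder"] = ratio(u["lad_len"], l["lad_len"])
    # temporal/nasal from whole-image ladder
    lad = brute_ladder(mask, spacing, strip)
    tn = {}
    for name, sl in (("t", np.s_[:, : mask.shape[1] // 2]), ("n", np.s_[:, mask.shape[1] // 2 :])):
        sub = lad[sl]
        runs = []
        for r in range(sub.shape[0]):
            run = 0
            for v in list(sub[r]) + [False]:
                if v:
                    run += 1
                elif run:
                    runs.append(run)
                    run = 0
        tn[name] = (
            float(sum(runs)) * scale,
            float(np.mean(runs)) * scale if runs else 0.0,
        )
    vals["temporal_nasal_diff_mean_diameter_ladder"] = tn["t"][1] - tn["n"][1]
    vals["temporal_nasal_diff_total_length_ladder"] = tn["t"][0] - tn["n"][0]
    vals["temporal_nasal_ratio_mean_diameter_ladder"] = ratio(tn["t"][1], tn["n"][1])
    vals["temporal_nasal_ratio_total_length_ladder"] = ratio(tn["t"][0], tn["n"][0])
    return vals


class TestToyMaskOracle:
    def test_all_28_features_match_first_principles(self, toy_mask):
        mask, _specs = toy_mask
        scale = 7 / 512
        image = np.where(mask, 75.0, 255.0)
        img = cv.EnFaceImage(image, "OD", scale)
        got = cv.compute_features(img)
        expected = _oracle_features(mask, scale)
        for c in FEATURE_COLUMNS:
            assert got[c] == pytest.approx(expected[c], abs=1e-9), c
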