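import math

import numpy as np
import pytest

import choroviz as cv
from choroviz.synth import _draw_capsule

from oracles import draw_capsule_mask


def make_mirror_symmetric_image(size: int = 256, seed: int = 3) -> cv.EnFaceImage:
    """Render strokes in the upper half and mirror them into the lower half,
    producing an exactly vertically mirror-symmetric 8-bit phantom."""
    canvas = np.full((size, size), 200.0)
    rng = np.random.default_rng(seed)
    for _ in range(5):
        r0 = rng.uniform(20, size // 2 - 20)
        c0 = rng.uniform(60, size - 20)
        theta = rng.uniform(105, 165)
        length = rng.uniform(0.3, 0.45) * size
        p1 = (
            r0 - length * math.sin(math.radians(theta)),
            c0 + length * math.cos(math.radians(theta)),
        )
        if p1[0] > r0:  # keep the stroke heading upward
            p1 = (2 * r0 - p1[0], 2 * c0 - p1[1])
        _draw_capsule(canvas, (r0, c0), p1, 2.5, 70.0, 200.0)
    # one counter-draining stroke so natural AND unnatural lengths are nonzero
    _draw_capsule(canvas, (size * 0.4, size * 0.15), (size * 0.23, size * 0.05), 2.0, 70.0, 200.0)
    upper = canvas[: size // 2].copy()
    full = np.round(np.vstack([upper, upper[::-1]]))
    return cv.EnFaceImage(full, "OD", cv.DEFAULT_SCALE_MM_PER_PX, "mirror_phantom")


def make_toy_two_stroke_mask(size: int = 64):
    """64x64 binary mask with one natural + one unnatural diagonal stroke in
    each hemifield, strokes mutually disjoint, 1-px margins from midline.

    Returns (mask, stroke_specs) where stroke_specs lists
    (hemifield, orientation_deg, p0, p1) in image coordinates.
    """
    mask = np.zeros((size, size), bool)
    specs = [
        # upper hemifield: natural (135 deg, down-right==up-left axis), unnatural (45)
        ("upper", 135.0, (4.0, 8.0), (24.0, 28.0)),
        ("upper", 45.0, (26.0, 38.0), (6.0, 58.0)),
        # lower hemifield: natural (45), unnatural (135)
        ("lower", 45.0, (58.0, 8.0), (38.0, 28.0)),
        ("lower", 135.0, (36.0, 38.0), (56.0, 58.0)),
    ]
    for _, _, p0, p1 in specs:
        draw_capsule_mask(mask, p0, p1, 1.6)
    return mask, specs


@pytest.fixture(scope="session")
def mirror_image() -> cv.EnFaceImage:
    return make_mirror_symmetric_image()


@pytest.fixture(scope="session")
def toy_mask():
    return make_toy_two_stroke_mask()


@pytest.fixture(scope="session")
def small_benchmark():
    """n=40 phantom dataset (alpha 0.1 vs 0.9) with features, for fast
    classifier tests."""
    samples = cv.generate_samples(
        40, cv.SynthConfig(alpha=0.1), cv.SynthConfig(alpha=0.9), seed=11
    )
    table = cv.feature_table_from_samples(samples)
    X, y = cv.split_xy(table)
    images = [s.image.pixels for s in samples]
    return samples, table, X, y, images


@pytest.fixture(scope="session")
def random_masks():
    """Morphologically closed random blobs for oracle-equivalence checks."""
    from scipy import ndimage

    rng = np.random.default_rng(42)
    masks = []
    for _ in range(20):
        m = ndimage.binary_closing(rng.random((64, 64)) < 0.45)
        masks.append(m)
    return masks
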