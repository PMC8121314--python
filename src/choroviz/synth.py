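"""Synthetic en-face phantoms with controllable hemifield asymmetry.

The generator emulates the appearance that the pipeline consumes: dark
branching vessel strokes on a brighter background, split by a horizontal
watershed line.  A single scalar knob ``alpha`` in [0, 1] controls how
asymmetric the rendered vasculature is:

* a fraction ``alpha`` of upper-hemifield strokes is drawn in the
  opposite (unnatural) drainage band — mimicking the clinical pattern
  in which one hemifield loses its drainage conformity — and may be
  started close enough to the watershed line to cross it;
* lower-hemifield stroke calibers are inflated by ``(1 + alpha)``.

Concentrating the band flips in one hemifield makes the expected
natural/unnatural contrast between hemifields increase monotonically
with ``alpha``.

``alpha = 0`` gives a vertically near-mirror-symmetric, drainage-
conformant phantom; ``alpha = 1`` a grossly asymmetric one.  The class
label is symmetric iff ``alpha < 0.5``.  Per-stroke ground truth
(hemifield, orientation, length, caliber) is returned alongside the
rendered image.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .core_io import DatasetManifest, EnFaceImage, ManifestRecord
from .config import DEFAULT_SCALE_MM_PER_PX


@dataclass(frozen=True)
class StrokeTruth:
    hemifield: str  # "upper" | "lower"
    orientation_deg: float
    length_px: float
    diameter_px: float
    band: str  # "natural" | "unnatural"


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; defaults target a 256 px desk-scale phantom."""

    image_size: int = 256
    n_trunks: int = 5  # per hemifield
    n_branches: int = 2  # per trunk
    diameter_px_mean: float = 5.0
    diameter_px_sd: float = 0.8
    vessel_intensity: float = 70.0
    background_intensity: float = 200.0
    noise_sd: float = 6.0
    alpha: float = 0.0
    label_threshold: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.vessel_intensity >= self.background_intensity:
            raise ValueError("vessels must be darker than the background")
        if self.n_trunks < 1:
            raise ValueError("need at least one trunk per hemifield")

    @property
    def label(self) -> str:
        return "symmetric" if self.alpha < self.label_threshold else "asymmetric"


@dataclass(frozen=True)
class SynthSample:
    image: EnFaceImage
    label: str
    alpha: float
    truth: tuple[StrokeTruth, ...]


def _draw_capsule(canvas, p0, p1, radius, vessel, background) -> None:
    """Render an anti-aliased thick line (min-blend for crossings)."""
    h, w = canvas.shape
    r0 = max(0, int(math.floor(min(p0[0], p1[0]) - radius - 1)))
    r1 = min(h, int(math.ceil(max(p0[0], p1[0]) + radius + 2)))
    c0 = max(0, int(math.floor(min(p0[1], p1[1]) - radius - 1)))
    c1 = min(w, int(math.ceil(max(p0[1], p1[1]) + radius + 2)))
    if r0 >= r1 or c0 >= c1:
        return
    ys, xs = np.mgrid[r0:r1, c0:c1]
    d = (p1[0] - p0[0], p1[1] - p0[1])
    l2 = d[0] * d[0] + d[1] * d[1]
    t = np.clip(((ys - p0[0]) * d[0] + (xs - p0[1]) * d[1]) / l2, 0.0, 1.0)
    dist = np.hypot(ys - (p0[0] + t * d[0]), xs - (p0[1] + t * d[1]))
    coverage = np.clip(radius + 0.5 - dist, 0.0, 1.0)
    patch = background - coverage * (background - vessel)
    canvas[r0:r1, c0:c1] = np.minimum(canvas[r0:r1, c0:c1], patch)


def _stroke_endpoints(rng, hemifield, band, size, crossing):
    """Start point and orientation for one trunk, in true-image frame."""
    h2 = size // 2
    margin = size // 16
    if band == "natural":
        theta = rng.uniform(105.0, 165.0) if hemifield == "upper" else rng.uniform(15.0, 75.0)
    else:
        theta = rng.uniform(15.0, 75.0) if hemifield == "upper" else rng.uniform(105.0, 165.0)
    length = rng.uniform(0.35, 0.55) * size
    if hemifield == "upper":
        row0 = h2 - margin if crossing else rng.uniform(h2 * 0.45, h2 - margin)
    else:
        row0 = h2 + margin if crossing else rng.uniform(h2 + margin, size - h2 * 0.45)
    col0 = rng.uniform(0.25 * size, 0.95 * size)
    # walk along orientation theta, choosing the sense that stays in-image
    drow = -math.sin(math.radians(theta))
    dcol = math.cos(math.radians(theta))
    if hemifield == "upper" and drow > 0:
        drow, dcol = -drow, -dcol
    if hemifield == "lower" and drow < 0:
        drow, dcol = -drow, -dcol
    if crossing:  # centre the stroke on the watershed line
        row0 = size // 2 - 0.5 * length * drow
    length = _clip_length((row0, col0), (drow, dcol), length, size)
    p1 = (row0 + length * drow, col0 + length * dcol)
    return (row0, col0), p1, theta, length


def _clip_length(p0, direction, length, size):
    """Shorten a stroke so it ends inside the canvas; truth lengths then
    match what is actually rendered."""
    t_max = length
    for start, step_ in zip(p0, direction):
        if step_ > 1e-12:
            t_max = min(t_max, (size - 2 - start) / step_)
        elif step_ < -1e-12:
            t_max = min(t_max, (1 - start) / step_)
    return max(4.0, t_max)


def generate_image(cfg: SynthConfig, seed: int) -> SynthSample:
    """Render one labelled phantom; deterministic per (cfg, seed)."""
    rng = np.random.default_rng(seed)
    size = cfg.image_size
    canvas = np.full((size, size), cfg.background_intensity, dtype=float)
    truth: list[StrokeTruth] = []
    for hemifield in ("upper", "lower"):
        caliber_scale = (1.0 + cfg.alpha) if hemifield == "lower" else 1.0
        for _ in range(cfg.n_trunks):
            flipped = hemifield == "upper" and rng.random() < cfg.alpha
            band = "unnatural" if flipped else "natural"
            crossing = flipped and rng.random() < cfg.alpha
            p0, p1, theta, length = _stroke_endpoints(rng, hemifield, band, size, crossing)
            diameter = max(
                1.5, rng.normal(cfg.diameter_px_mean, cfg.diameter_px_sd)
            ) * caliber_scale
            _draw_capsule(
                canvas, p0, p1, diameter / 2.0, cfg.vessel_intensity, cfg.background_intensity
            )
            truth.append(StrokeTruth(hemifield, theta, length, diameter, band))
            for _ in range(cfg.n_branches):
                t = rng.uniform(0.3, 0.8)
                b0 = (p0[0] + t * (p1[0] - p0[0]), p0[1] + t * (p1[1] - p0[1]))
                # branch stays inside the stroke's band (+/- 20 deg, clipped)
                if band == ("natural" if hemifield == "upper" else "unnatural"):
                    lo, hi = 100.0, 170.0
                else:
                    lo, hi = 10.0, 80.0
                btheta = float(np.clip(theta + rng.uniform(-20, 20), lo, hi))
                blen = length * rng.uniform(0.3, 0.5)
                bdrow = -math.sin(math.radians(btheta))
                bdcol = math.cos(math.radians(btheta))
                if hemifield == "upper" and bdrow > 0:
                    bdrow, bdcol = -bdrow, -bdcol
                if hemifield == "lower" and bdrow < 0:
                    bdrow, bdcol = -bdrow, -bdcol
                bdiam = diameter * rng.uniform(0.5, 0.8)
                blen = _clip_length(b0, (bdrow, bdcol), blen, size)
                b1 = (b0[0] + blen * bdrow, b0[1] + blen * bdcol)
                _draw_capsule(
                    canvas, b0, b1, bdiam / 2.0, cfg.vessel_intensity, cfg.background_intensity
                )
                truth.append(StrokeTruth(hemifield, btheta, blen, bdiam, band))
    if cfg.noise_sd > 0:
        canvas = canvas + rng.normal(0.0, cfg.noise_sd, canvas.shape)
    canvas = np.clip(np.round(canvas), 0, 255).astype(np.uint8).astype(float)
    img = EnFaceImage(
        canvas,
        laterality="OD",
        scale_mm_per_px=DEFAULT_SCALE_MM_PER_PX * 512.0 / size,
        eye_id=f"synth_{seed}",
    )
    return SynthSample(img, cfg.label, cfg.alpha, tuple(truth))


def generate_samples(
    n: int,
    cfg_symmetric: SynthConfig,
    cfg_asymmetric: SynthConfig,
    seed: int,
    class_balance: float = 0.5,
) -> list[SynthSample]:
    """Generate ``n`` labelled samples (in memory), per-sample seeds
    derived from the master seed."""
    if n < 2:
        raise ValueError("need n >= 2")
    n_sym = int(round(n * class_balance))
    samples = []
    for i in range(n):
        cfg = cfg_symmetric if i < n_sym else cfg_asymmetric
        sub_seed = (seed * 100003 + i) % (2**31 - 1)
        s = generate_image(cfg, sub_seed)
        s = SynthSample(
            EnFaceImage(
                s.image.pixels, "OD", s.image.scale_mm_per_px, eye_id=f"eye{i:04d}"
            ),
            s.label,
            s.alpha,
            s.truth,
        )
        samples.append(s)
    return samples


def generate_dataset(
    n: int,
    cfg_symmetric: SynthConfig,
    cfg_asymmetric: SynthConfig,
    out_dir: str | Path,
    seed: int,
    class_balance: float = 0.5,
) -> DatasetManifest:
    """Write ``n`` phantom PNGs plus a manifest CSV to ``out_dir``."""
    from .core_io import write_manifest

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    samples = generate_samples(n, cfg_symmetric, cfg_asymmetric, seed, class_balance)
    records = []
    for s in samples:
        fname = f"{s.image.eye_id}.png"
        Image.fromarray(s.image.pixels.astype(np.uint8)).save(out_dir / fname)
        records.append(
            ManifestRecord(
                eye_id=s.image.eye_id,
                image_path=fname,
                label=s.label,
                laterality="OD",
            )
        )
    manifest = DatasetManifest(tuple(records))
    write_manifest(manifest, out_dir / "manifest.csv")
    return manifest
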