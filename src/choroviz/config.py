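"""Pipeline configuration.

All tunable knobs of the feature-extraction pipeline live here so that a
feature table is fully determined by (image, PipelineConfig).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

#: Default physical scale: a 7 x 7 mm macular scan rendered as 512 x 512 px.
DEFAULT_SCALE_MM_PER_PX = 7.0 / 512.0


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs of the en-face vessel quantification pipeline.

    Parameters
    ----------
    scale_mm_per_px : mm per pixel; every mm-valued feature uses it.
    min_component_px : speckle/hole size removed by denoising, stated at a
        512 x 512 reference resolution and rescaled by (H/512)**2.
    min_segment_px : skeleton segments shorter than this (path pixels) are
        excluded from orientation statistics (kept in length totals).
    ladder_spacing_px, ladder_strip_px : horizontal sampling lines every
        ``spacing`` rows, majority vote over a ``strip``-row window.
    ratio_cap : sentinel for ratio features with zero denominators; keeps
        feature vectors finite for downstream classifiers.
    strict_od : if True, left (OS) eyes are rejected instead of mirrored.
    abs_ladder_diff : report ladder difference features as absolute values
        instead of signed (upper-lower, temporal-nasal).
    """

    scale_mm_per_px: float = DEFAULT_SCALE_MM_PER_PX
    min_component_px: int = 30
    min_segment_px: int = 5
    ladder_spacing_px: int = 25
    ladder_strip_px: int = 7
    ratio_cap: float = 100.0
    strict_od: bool = False
    abs_ladder_diff: bool = False

    def __post_init__(self) -> None:
        if self.scale_mm_per_px <= 0:
            raise ValueError("scale_mm_per_px must be positive")
        if self.ladder_strip_px % 2 == 0:
            raise ValueError("ladder strip width must be odd")
        if self.ladder_spacing_px < self.ladder_strip_px:
            raise ValueError("ladder spacing must be >= strip width")

    def min_component_for(self, height: int) -> int:
        """Denoising size threshold rescaled to the image resolution."""
        return max(1, round(self.min_component_px * (height / 512.0) ** 2))

    def to_dict(self) -> dict:
        return asdict(self)


DEFAULT_CONFIG = PipelineConfig()
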