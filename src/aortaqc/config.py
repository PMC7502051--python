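"""Run configuration: every tunable of the pipeline with its default.

Defaults mirror the published parameters of the method (existence threshold
0.6, SOI-2 offset 230 mm = 46 slices at 5 mm z-spacing, six Hough
candidates, five-slice path, selection threshold 200, 4-pixel radius
reduction, the Table-1 category boundaries). Parameters the method left
unspecified (edge threshold, variance normalization, bone threshold,
vesselness scales) carry this package's documented conventions and are
equally overridable from YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    # --- slice detection -------------------------------------------------
    #: a SOI whose best NCC is below this is declared non-existing
    existence_threshold: float = 0.6
    #: physical SOI-2 fallback offset; converted to slices via z-spacing
    offset_mm: float = 230.0
    #: fraction of slices searched per SOI ("upper/lower two thirds")
    search_fraction: float = 2.0 / 3.0
    #: templates (or template sets) per SOI when building a bank
    templates_per_soi: int = 3

    # --- aortic ROI (circle Hough + dynamic programming) -----------------
    #: physiological aortic radius range, mm
    radius_range_mm: tuple[float, float] = (8.0, 25.0)
    #: gradient-magnitude edge threshold, HU per pixel
    edge_threshold: float = 100.0
    #: number of Hough accumulator peaks kept as aorta candidates
    top_k: int = 6
    #: minimum normalized accumulator score for a peak to count as a candidate
    hough_min_score: float = 0.1
    #: slices per candidate path
    path_length: int = 5
    #: a path must score strictly below this to be accepted
    cost_threshold: float = 200.0
    #: HU^2 normalization of the variance cost term
    variance_norm_v0: float = 100.0
    #: radius reduction applied before measuring, in pixels
    radius_reduction_px: int = 4

    # --- femoral ROI (vesselness) ----------------------------------------
    vessel_scales_mm: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0)
    bone_threshold_hu: float = 600.0
    bone_dilation_px: int = 2
    min_response: float = 0.1
    #: anterior-medial acceptance band relative to a femoral-head hit, px
    search_band_px: int = 30
    #: minimum medial offset from the head hit; separates the artery from
    #: responses at the head itself (template hits are only head-accurate
    #: to a few px)
    search_band_min_medial_px: int = 6

    # --- classification ---------------------------------------------------
    category_boundaries: tuple[float, float, float, float] = (180.0, 240.0, 300.0, 360.0)
    total_coverage: bool = False

    def offset_slices(self, z_spacing: float) -> int:
        """Physical offset converted to slices (rounded half up)."""
        return int(self.offset_mm / z_spacing + 0.5)

    def radius_range_px(self, in_plane_spacing: float) -> tuple[int, int]:
        lo, hi = self.radius_range_mm
        return (
            max(1, int(round(lo / in_plane_spacing))),
            max(1, int(round(hi / in_plane_spacing))),
        )

    def vessel_scales_px(self, in_plane_spacing: float) -> tuple[float, ...]:
        return tuple(s / in_plane_spacing for s in self.vessel_scales_mm)

    # --- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name: f for f in dataclasses.fields(cls)}
        unknown = set(data) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for name, value in data.items():
            if isinstance(value, list):
                value = tuple(value)
            kwargs[name] = value
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


def default_config_path() -> Path:
    """Path of the committed defaults file shipped with the package."""
    return Path(__file__).parent / "data" / "defaults.yaml"
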