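"""Synthetic CTA phantoms with exactly known ground truth.

No clinical CTA data ships with this package, so every pipeline stage is
exercised on generated volumes that emulate the structures the method keys
on: the aorta as a bright quasi-circular tube with a gentle center drift, a
pulmonary-bifurcation-like landmark on one slice, paired femoral-head
landmarks, small bright common femoral arteries anterior-medial to the
heads, a vertebral-body decoy (a circular structure the aorta selector must
reject), and an optional calcified ring on the aortic wall. Lumen HU is
configurable per ROI so phantoms can be placed in any contrast category.

Rendering is deliberately simple: structures are painted as hard-edged
discs/annuli by center-of-voxel inclusion (no anti-aliasing, no CT physics),
which makes brute-force oracles exact. The femoral head is rendered as a
bright cortical shell over a moderate trabecular interior, and the vertebral
body gets a darker core: both choices echo real attenuation structure and
keep the landmark templates from pseudo-matching the other bright circular
structures.

Ground-truth ROI means are measured on the *rendered* voxels inside the
(radius-reduced) ground-truth masks — not taken from the nominal lumen HU —
so partial effects of noise or overlap can never desynchronize the expected
values from the volume. Expected categories and the expected class are
recomputed from those means through :mod:`aortaqc.classify`, keeping the
rule tables a single source of truth.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .classify import categorize as _categorize
from .classify import classify as _classify
from .templates import SOI1, SOI3_LEFT, SOI3_RIGHT, Template, TemplateSet
from .volume_io import Volume


# ---------------------------------------------------------------------------
# specification


@dataclass
class AortaSpec:
    center: tuple[float, float] = (62.0, 60.0)  # (row, col) px
    radius_px: float = 10.0
    drift_amplitude_px: float = 1.5
    drift_period_slices: float = 48.0
    hu_thoracic: float = 270.0
    hu_abdominal: float = 270.0
    #: first slice measured with the abdominal HU
    segment_boundary_slice: int = 36
    extent: tuple[int, int] = (2, 90)  # [start, stop)

    def center_at(self, slice_index: int) -> tuple[float, float]:
        phase = 2 * math.pi * slice_index / self.drift_period_slices
        return (
            self.center[0] + self.drift_amplitude_px * math.sin(phase),
            self.center[1] + self.drift_amplitude_px * math.cos(phase),
        )

    def hu_at(self, slice_index: int) -> float:
        return self.hu_thoracic if slice_index < self.segment_boundary_slice else self.hu_abdominal


@dataclass
class VertebraSpec:
    center: tuple[float, float] = (40.0, 64.0)
    radius_px: float = 9.0
    hu: float = 400.0
    core_radius_px: float = 5.0
    core_hu: float = 150.0
    extent: tuple[int, int] | None = None  # None -> full volume


@dataclass
class BifurcationSpec:
    slice_index: int = 20
    center: tuple[float, float] = (92.0, 64.0)
    hu: float = 240.0
    pattern_id: int = 0


@dataclass
class FemoralSpec:
    slice_index: int = 72
    centers: tuple[tuple[float, float], tuple[float, float]] = ((78.0, 38.0), (78.0, 90.0))
    head_radius_px: float = 14.0
    shell_thickness_px: float = 2.0
    shell_hu: float = 700.0
    interior_hu: float = 300.0


@dataclass
class FemoralArterySpec:
    centers: tuple[tuple[float, float], tuple[float, float]] = ((94.0, 56.0), (94.0, 72.0))
    radius_px: float = 3.0
    hu: float = 270.0
    extent: tuple[int, int] = (68, 78)


@dataclass
class CalcificationSpec:
    enabled: bool = False
    thickness_px: float = 2.0
    hu: float = 1000.0


@dataclass
class PhantomSpec:
    """Full description of a synthetic CTA volume.

    The seed drives only the additive Gaussian noise; geometry is
    deterministic, so two specs differing only in seed render identical
    volumes at ``noise_sigma_hu = 0``. Set a structure to ``None`` to omit
    it (e.g. ``femoral=None`` for a scan that ends above the femoral heads).
    """

    shape: tuple[int, int, int] = (96, 128, 128)  # (slices, rows, cols)
    spacing: tuple[float, float, float] = (1.0, 1.0, 5.0)  # (x, y, z) mm
    background_hu: float = 40.0
    noise_sigma_hu: float = 10.0
    seed: int = 0
    aorta: AortaSpec | None = field(default_factory=AortaSpec)
    vertebra: VertebraSpec | None = field(default_factory=VertebraSpec)
    bifurcation: BifurcationSpec | None = field(default_factory=BifurcationSpec)
    femoral: FemoralSpec | None = field(default_factory=FemoralSpec)
    arteries: FemoralArterySpec | None = field(default_factory=FemoralArterySpec)
    calcification: CalcificationSpec = field(default_factory=CalcificationSpec)

    def validate(self) -> None:
        ns, nr, nc = self.shape
        def _inside(center, radius):
            r, c = center
            return radius <= r <= nr - 1 - radius and radius <= c <= nc - 1 - radius

        if self.aorta is not None:
            a = self.aorta
            pad = a.radius_px + a.drift_amplitude_px
            if not _inside(a.center, pad):
                raise ValueError("aorta does not fit inside the volume")
            if not (0 <= a.extent[0] < a.extent[1] <= ns):
                raise ValueError("aorta extent outside the volume")
        if self.vertebra is not None and not _inside(self.vertebra.center, self.vertebra.radius_px):
            raise ValueError("vertebral decoy does not fit inside the volume")
        if self.bifurcation is not None and not (0 <= self.bifurcation.slice_index < ns):
            raise ValueError("bifurcation slice outside the volume")
        if self.femoral is not None:
            f = self.femoral
            if not (0 <= f.slice_index < ns):
                raise ValueError("femoral-head slice outside the volume")
            for c in f.centers:
                if not _inside(c, f.head_radius_px):
                    raise ValueError("femoral head does not fit inside the volume")
        if self.bifurcation is not None and self.femoral is not None:
            if not self.bifurcation.slice_index < self.femoral.slice_index:
                raise ValueError(
                    "landmark slices must be distinct and ordered: "
                    "bifurcation above the femoral heads"
                )
        if self.arteries is not None:
            for c in self.arteries.centers:
                if not _inside(c, self.arteries.radius_px):
                    raise ValueError("femoral artery does not fit inside the volume")

    # -- (de)serialization --------------------------------------------------
    def to_dict(self) -> dict:
        return _asdict_clean(dataclasses.asdict(self))

    @classmethod
    def from_dict(cls, data: dict) -> "PhantomSpec":
        sub = {
            "aorta": AortaSpec,
            "vertebra": VertebraSpec,
            "bifurcation": BifurcationSpec,
            "femoral": FemoralSpec,
            "arteries": FemoralArterySpec,
            "calcification": CalcificationSpec,
        }
        kwargs: dict = {}
        for key, value in data.items():
            if key in sub:
                kwargs[key] = None if value is None else sub[key](**_tuplify(value))
            else:
                kwargs[key] = _tuplify_value(value)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhantomSpec":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


def _tuplify_value(v):
    if isinstance(v, list):
        return tuple(_tuplify_value(x) for x in v)
    return v


def _tuplify(d: dict) -> dict:
    return {k: _tuplify_value(v) for k, v in d.items()}


def _asdict_clean(v):
    if isinstance(v, dict):
        return {k: _asdict_clean(x) for k, x in v.items()}
    if isinstance(v, tuple):
        return [_asdict_clean(x) for x in v]
    return v


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class GroundTruth:
    """Everything the pipeline should recover from a phantom."""

    soi1: int | None
    soi2: int | None
    soi3: int | None
    #: slice index -> (row, col, radius) of the painted aortic circle
    aorta_circles: dict[int, tuple[float, float, float]]
    #: (row, col, radius) of the femoral artery discs on SOI 3
    femoral_discs: list[tuple[float, float, float]]
    #: roi_id -> mean HU of the rendered voxels in the ground-truth mask
    expected_mean_hu: dict[int, float]
    #: roi_id -> category label, recomputed from expected_mean_hu
    expected_category: dict[int, str]
    #: "1" | "2" | "3" | "indeterminate" | None (fewer than 2 ROIs)
    expected_class: str | None

    def to_json(self) -> str:
        data = {
            "soi1": self.soi1,
            "soi2": self.soi2,
            "soi3": self.soi3,
            "aorta_circles": {str(k): list(v) for k, v in sorted(self.aorta_circles.items())},
            "femoral_discs": [list(d) for d in self.femoral_discs],
            "expected_mean_hu": {str(k): round(v, 6) for k, v in sorted(self.expected_mean_hu.items())},
            "expected_category": {str(k): v for k, v in sorted(self.expected_category.items())},
            "expected_class": self.expected_class,
        }
        return json.dumps(data, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            soi1=d["soi1"],
            soi2=d["soi2"],
            soi3=d["soi3"],
            aorta_circles={int(k): tuple(v) for k, v in d["aorta_circles"].items()},
            femoral_discs=[tuple(x) for x in d["femoral_discs"]],
            expected_mean_hu={int(k): v for k, v in d["expected_mean_hu"].items()},
            expected_category={int(k): v for k, v in d["expected_category"].items()},
            expected_class=d["expected_class"],
        )


# ---------------------------------------------------------------------------
# rendering


def disc_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    """Hard-edged disc by center-of-voxel inclusion (<= radius)."""
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def annulus_mask(
    shape: tuple[int, int], center: tuple[float, float], r_inner: float, r_outer: float
) -> np.ndarray:
    """Pixels with r_inner < distance <= r_outer."""
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    return (d2 > r_inner**2) & (d2 <= r_outer**2)


def _bifurcation_discs(spec: BifurcationSpec) -> list[tuple[float, float, float]]:
    """Disc layout (row, col, radius) of the bifurcation-like landmark."""
    r0, c0 = spec.center
    if spec.pattern_id == 0:
        return [(r0, c0 - 14, 5.0), (r0 + 2, c0, 4.0), (r0, c0 + 14, 5.0)]
    # slight anatomical variant: asymmetric branch take-off
    return [(r0 - 1, c0 - 13, 5.0), (r0 + 3, c0 + 1, 4.0), (r0 + 1, c0 + 15, 5.0)]


def generate_phantom(
    spec: PhantomSpec,
    radius_reduction_px: int = 4,
    soi2_offset_mm: float = 230.0,
) -> tuple[Volume, GroundTruth]:
    """Render a phantom volume and its ground truth.

    ``radius_reduction_px`` and ``soi2_offset_mm`` mirror the pipeline
    defaults so that ground-truth ROI masks (reduced aortic discs, SOI-2
    placement when a landmark is absent) describe what a correctly working
    pipeline at default configuration should measure.
    """
    spec.validate()
    ns, nr, nc = spec.shape
    vol = np.full(spec.shape, spec.background_hu, dtype=np.float64)
    sl_shape = (nr, nc)

    if spec.vertebra is not None:
        v = spec.vertebra
        lo, hi = v.extent if v.extent is not None else (0, ns)
        body = disc_mask(sl_shape, v.center, v.radius_px)
        core = disc_mask(sl_shape, v.center, v.core_radius_px)
        for i in range(lo, hi):
            vol[i][body] = v.hu
            vol[i][core] = v.core_hu

    aorta_circles: dict[int, tuple[float, float, float]] = {}
    if spec.aorta is not None:
        a = spec.aorta
        for i in range(*a.extent):
            center = a.center_at(i)
            vol[i][disc_mask(sl_shape, center, a.radius_px)] = a.hu_at(i)
            if spec.calcification.enabled:
                ring = annulus_mask(
                    sl_shape, center, a.radius_px - spec.calcification.thickness_px, a.radius_px
                )
                vol[i][ring] = spec.calcification.hu
            aorta_circles[i] = (center[0], center[1], a.radius_px)

    if spec.bifurcation is not None:
        b = spec.bifurcation
        for r, c, rad in _bifurcation_discs(b):
            vol[b.slice_index][disc_mask(sl_shape, (r, c), rad)] = b.hu

    if spec.femoral is not None:
        f = spec.femoral
        for center in f.centers:
            shell = annulus_mask(
                sl_shape, center, f.head_radius_px - f.shell_thickness_px, f.head_radius_px
            )
            interior = disc_mask(sl_shape, center, f.head_radius_px - f.shell_thickness_px)
            vol[f.slice_index][interior] = f.interior_hu
            vol[f.slice_index][shell] = f.shell_hu

    femoral_discs: list[tuple[float, float, float]] = []
    if spec.arteries is not None:
        fa = spec.arteries
        for i in range(*fa.extent):
            for center in fa.centers:
                vol[i][disc_mask(sl_shape, center, fa.radius_px)] = fa.hu
        femoral_discs = [(c[0], c[1], fa.radius_px) for c in fa.centers]

    if spec.noise_sigma_hu > 0:
        rng = np.random.default_rng(spec.seed)
        vol += rng.normal(0.0, spec.noise_sigma_hu, size=vol.shape)

    volume = Volume(vol, spec.spacing, source=f"phantom(seed={spec.seed})")
    gt = _ground_truth(spec, volume, aorta_circles, femoral_discs,
                       radius_reduction_px, soi2_offset_mm)
    return volume, gt


def _ground_truth(
    spec: PhantomSpec,
    volume: Volume,
    aorta_circles: dict[int, tuple[float, float, float]],
    femoral_discs: list[tuple[float, float, float]],
    radius_reduction_px: int,
    soi2_offset_mm: float,
) -> GroundTruth:
    ns = spec.shape[0]
    sl_shape = spec.shape[1:]
    soi1 = spec.bifurcation.slice_index if spec.bifurcation is not None else None
    soi3 = spec.femoral.slice_index if spec.femoral is not None else None
    offset = int(soi2_offset_mm / spec.spacing[2] + 0.5)
    if soi1 is not None and soi3 is not None:
        soi2: int | None = math.floor((soi1 + soi3) / 2 + 0.5)
    elif soi1 is not None:
        soi2 = min(ns - 1, soi1 + offset)
    elif soi3 is not None:
        soi2 = max(0, soi3 - offset)
    else:
        soi2 = None

    means: dict[int, float] = {}
    for roi_id, soi in ((1, soi1), (2, soi2)):
        if soi is None or soi not in aorta_circles:
            continue
        r0, c0, rad = aorta_circles[soi]
        reduced = max(rad - radius_reduction_px, 1.0)
        mask = disc_mask(sl_shape, (r0, c0), reduced)
        means[roi_id] = float(volume.voxels[soi][mask].mean())
    if soi3 is not None and femoral_discs:
        masks = [disc_mask(sl_shape, (r, c), rad) for r, c, rad in femoral_discs]
        union = np.logical_or.reduce(masks)
        means[3] = float(volume.voxels[soi3][union].mean())

    categories = {k: _categorize(v).value for k, v in means.items()}
    if len(categories) >= 2:
        expected_class: str | None = _classify(
            [categories[k] for k in sorted(categories)]
        ).label
    else:
        expected_class = None
    return GroundTruth(
        soi1, soi2, soi3, aorta_circles, femoral_discs, means, categories, expected_class
    )


# ---------------------------------------------------------------------------
# template extraction


def extract_template(
    volume: Volume,
    slice_index: int,
    bounding_box: tuple[int, int, int, int],
    soi_label: str = SOI1,
) -> Template:
    """Cut a 2D patch ``(row0, col0, height, width)`` out of a slice.

    The patch carries the source volume's in-plane spacing, so it can later
    be resampled to a differently sampled volume before matching.
    """
    r0, c0, h, w = bounding_box
    rows, cols = volume.slice_shape
    if not (0 <= slice_index < volume.n_slices):
        raise IndexError(f"slice {slice_index} outside the volume")
    if r0 < 0 or c0 < 0 or h < 1 or w < 1 or r0 + h > rows or c0 + w > cols:
        raise IndexError(f"bounding box {bounding_box} outside the slice {rows}x{cols}")
    patch = volume.voxels[slice_index, r0 : r0 + h, c0 : c0 + w].copy()
    return Template(patch, volume.in_plane_spacing, soi_label)


_JITTERS = [(0, 0), (-2, 2), (2, -2), (-3, -1), (1, 3)]


def build_template_bank(
    volume: Volume, spec: PhantomSpec, templates_per_soi: int = 3
) -> list[TemplateSet]:
    """Extract a template bank from a phantom at its known landmarks.

    Produces ``templates_per_soi`` single-template sets for SOI 1 and the
    same number of left/right femoral-head pairs for SOI 3, with slightly
    jittered bounding boxes standing in for the variability of patches cut
    from different reference studies.
    """
    if templates_per_soi < 1 or templates_per_soi > len(_JITTERS):
        raise ValueError(f"templates_per_soi must be in 1..{len(_JITTERS)}")
    sets: list[TemplateSet] = []
    if spec.bifurcation is not None:
        b = spec.bifurcation
        r0, c0 = int(b.center[0]), int(b.center[1])
        for j, (dr, dc) in enumerate(_JITTERS[:templates_per_soi]):
            box = (r0 - 9 + dr, c0 - 22 + dc, 19, 45)
            tpl = extract_template(volume, b.slice_index, box, SOI1)
            sets.append(TemplateSet([tpl], f"soi1_{j}"))
    if spec.femoral is not None:
        f = spec.femoral
        half = int(f.head_radius_px) + 2
        for j, (dr, dc) in enumerate(_JITTERS[:templates_per_soi]):
            members = []
            for center, label in zip(f.centers, (SOI3_LEFT, SOI3_RIGHT)):
                r0, c0 = int(center[0]), int(center[1])
                box = (r0 - half + dr, c0 - half + dc, 2 * half + 1, 2 * half + 1)
                members.append(extract_template(volume, f.slice_index, box, label))
            sets.append(TemplateSet(members, f"soi3_{j}"))
    return sets
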