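"""Slice-of-interest detection by template matching.

The similarity function is the zero-mean normalized cross-correlation
(Pearson form), chosen for its invariance to affine intensity maps with
positive gain: the absolute HU level of contrast-filled structures varies
strongly between studies, their spatial pattern much less.

For each candidate slice, every template is slid over the slice at stride
1 px (full-overlap windows only) and its best NCC recorded; a template
set's score is the mean of its members' maxima. The slice with the highest
score over the search space wins. A best score below the existence
threshold (default 0.6) declares the SOI non-existing; SOI 2 is then
derived from the remaining SOI by a fixed physical offset instead of the
mean of SOI 1 and 3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage, signal

from .templates import Template, TemplateSet
from .volume_io import Volume

FOUND = "found"
MISSING = "missing"
DERIVED_MEAN = "derived_mean"
DERIVED_OFFSET = "derived_offset"


@dataclass
class SoiResult:
    """Outcome of locating one slice of interest."""

    soi_id: int
    status: str
    slice_index: int | None = None
    best_similarity: float | None = None
    #: per-member (row, col) centers of the best match on the winning slice
    template_hits: list[tuple[int, int]] = field(default_factory=list)
    clamped: bool = False

    def to_dict(self) -> dict:
        return {
            "soi_id": self.soi_id,
            "status": self.status,
            "slice_index": self.slice_index,
            "best_similarity": None
            if self.best_similarity is None
            else round(float(self.best_similarity), 6),
            "template_hits": [list(h) for h in self.template_hits],
            "clamped": self.clamped,
        }


# ---------------------------------------------------------------------------
# normalized cross-correlation


def ncc(template_patch: np.ndarray, image_patch: np.ndarray) -> float:
    """Zero-mean normalized cross-correlation of two same-shape patches.

    Returns a value in [-1, 1]. A zero-variance template is an error (the
    measure is undefined); a zero-variance image patch yields 0 by
    definition — a flat window carries no pattern to correlate with.
    """
    a = np.asarray(template_patch, dtype=np.float64)
    b = np.asarray(image_patch, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"patch shapes differ: {a.shape} vs {b.shape}")
    za = a - a.mean()
    na = float(np.sqrt(np.sum(za * za)))
    if na == 0.0:
        raise ValueError("template patch has zero variance; NCC undefined")
    zb = b - b.mean()
    nb = float(np.sqrt(np.sum(zb * zb)))
    if nb == 0.0:
        return 0.0
    return float(np.clip(np.sum(za * zb) / (na * nb), -1.0, 1.0))


def sliding_ncc(image: np.ndarray, template: np.ndarray) -> np.ndarray:
    """NCC of a template against every full-overlap window of an image.

    Output shape is ``(H - h + 1, W - w + 1)``; entry ``(i, j)`` is
    ``ncc(template, image[i:i+h, j:j+w])``. Computed exactly via an FFT
    correlation for the numerator and integral images for the per-window
    mean/variance; windows with zero variance map to 0.
    """
    img = np.asarray(image, dtype=np.float64)
    tpl = np.asarray(template, dtype=np.float64)
    if tpl.shape[0] > img.shape[0] or tpl.shape[1] > img.shape[1]:
        raise ValueError(
            f"template {tpl.shape} larger than image {img.shape}"
        )
    zt = tpl - tpl.mean()
    nt = float(np.sqrt(np.sum(zt * zt)))
    if nt == 0.0:
        raise ValueError("template patch has zero variance; NCC undefined")
    # numerator: sum_w (w - w_mean) * zt == correlate(img, zt) since sum(zt)=0
    num = signal.fftconvolve(img, zt[::-1, ::-1], mode="valid")
    # per-window sum and sum of squares via integral images
    area = tpl.size
    ones = np.ones(tpl.shape)
    wsum = signal.fftconvolve(img, ones, mode="valid")
    wsum2 = signal.fftconvolve(img * img, ones, mode="valid")
    wvar = wsum2 - wsum * wsum / area
    wvar = np.maximum(wvar, 0.0)
    denom = nt * np.sqrt(wvar)
    # tolerance scaled to the data: FFT round-off on a truly flat window
    eps = 1e-9 * max(1.0, float(np.abs(img).max()) ** 2 * area)
    out = np.zeros_like(num)
    good = denom > eps
    out[good] = num[good] / denom[good]
    return np.clip(out, -1.0, 1.0)


def resample_template(template: Template, target_spacing: tuple[float, float]) -> Template:
    """Resample a template patch to a target in-plane (x, y) spacing.

    Linear interpolation; a no-op when spacings already agree.
    """
    sx, sy = template.source_spacing
    tx, ty = target_spacing
    if abs(sx - tx) < 1e-9 and abs(sy - ty) < 1e-9:
        return template
    # rows are spaced by y, columns by x
    factors = (sy / ty, sx / tx)
    patch = ndimage.zoom(template.patch, factors, order=1)
    return Template(patch, (tx, ty), template.soi_label)


def _member_maxima(
    slice_2d: np.ndarray, members: Sequence[Template]
) -> list[tuple[float, tuple[int, int]]]:
    """Best NCC and matched-window center for each set member."""
    out = []
    for tpl in members:
        nmap = sliding_ncc(slice_2d, tpl.patch)
        idx = np.unravel_index(int(np.argmax(nmap)), nmap.shape)
        h, w = tpl.patch.shape
        center = (int(idx[0]) + h // 2, int(idx[1]) + w // 2)
        out.append((float(nmap[idx]), center))
    return out


def slice_similarity(volume: Volume, slice_index: int, template_set: TemplateSet) -> float:
    """Set score on one slice: mean of the members' best sliding-window NCC.

    Templates are resampled to the volume's in-plane spacing first.
    """
    members = [resample_template(m, volume.in_plane_spacing) for m in template_set.members]
    maxima = _member_maxima(volume.voxels[slice_index], members)
    return float(np.mean([m[0] for m in maxima]))


# ---------------------------------------------------------------------------
# SOI search


def upper_two_thirds(n_slices: int, fraction: float = 2.0 / 3.0) -> range:
    """The most superior ``ceil(fraction * n)`` slice indices."""
    return range(0, math.ceil(fraction * n_slices))


def lower_two_thirds(n_slices: int, fraction: float = 2.0 / 3.0) -> range:
    """The most inferior ``ceil(fraction * n)`` slice indices."""
    return range(n_slices - math.ceil(fraction * n_slices), n_slices)


def detect_soi(
    volume: Volume,
    candidate_sets: Sequence[TemplateSet],
    search_space: Iterable[int],
    existence_threshold: float = 0.6,
) -> SoiResult:
    """Find one SOI: argmax of the set score over (slice, candidate set).

    Ties are broken toward the smaller slice index. The SOI exists iff the
    best score reaches the existence threshold (the boundary is inclusive:
    only a score strictly below it declares the SOI missing).
    """
    if volume.n_slices < 3:
        raise ValueError("volume has fewer than 3 slices; SOI search undefined")
    if not candidate_sets:
        raise ValueError("no candidate template sets given")
    soi_ids = {s.soi_id for s in candidate_sets}
    if len(soi_ids) != 1:
        raise ValueError("candidate sets mix SOI labels")
    soi_id = soi_ids.pop()

    resampled = [
        TemplateSet(
            [resample_template(m, volume.in_plane_spacing) for m in s.members], s.set_id
        )
        for s in candidate_sets
    ]
    rows, cols = volume.slice_shape
    for s in resampled:
        for m in s.members:
            if m.patch.shape[0] > rows or m.patch.shape[1] > cols:
                raise ValueError(
                    f"template of set {s.set_id} larger than the slice after resampling"
                )

    best_score = -np.inf
    best_slice: int | None = None
    best_hits: list[tuple[int, int]] = []
    for idx in search_space:
        slice_2d = volume.voxels[idx]
        for tset in resampled:
            maxima = _member_maxima(slice_2d, tset.members)
            score = float(np.mean([m[0] for m in maxima]))
            if score > best_score:
                best_score = score
                best_slice = int(idx)
                best_hits = [m[1] for m in maxima]
    if best_slice is None:
        raise ValueError("empty search space")
    if best_score < existence_threshold:
        return SoiResult(soi_id, MISSING, None, best_score)
    return SoiResult(soi_id, FOUND, best_slice, best_score, best_hits)


def derive_soi2(
    soi1: SoiResult,
    soi3: SoiResult,
    offset_slices: int,
    n_slices: int,
) -> SoiResult:
    """Place SOI 2 from SOI 1 and 3.

    Standard case (both found): the arithmetic mean of the two slice
    indices, rounded half up. If only one exists, a fixed offset — half the
    average SOI1-SOI3 distance, 46 slices / 230 mm at 5 mm z-spacing — is
    applied toward the missing side. The result is clamped to the volume
    (flagged via ``clamped``). Both missing is an error: SOI 2 cannot be
    determined and the caller proceeds with the remaining ROIs.
    """
    have1 = soi1.status == FOUND
    have3 = soi3.status == FOUND
    if have1 and have3:
        idx = math.floor((soi1.slice_index + soi3.slice_index) / 2 + 0.5)
        status = DERIVED_MEAN
    elif have1:
        idx = soi1.slice_index + offset_slices
        status = DERIVED_OFFSET
    elif have3:
        idx = soi3.slice_index - offset_slices
        status = DERIVED_OFFSET
    else:
        raise ValueError("SOI 2 underivable: neither SOI 1 nor SOI 3 was found")
    clamped = not (0 <= idx < n_slices)
    idx = int(np.clip(idx, 0, n_slices - 1))
    return SoiResult(2, status, idx, None, clamped=clamped)
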