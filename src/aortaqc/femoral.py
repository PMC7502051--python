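"""Femoral ROI localization with a 2D multiscale vesselness filter.

The common femoral artery is too small for the circle Hough approach, so
ROI 3 is placed from a Hessian-eigenvalue vesselness response on the SOI-3
slice: at each scale the image is smoothed with a Gaussian, the Hessian's
scale-normalized eigenvalues computed, and bright tubular/blob structures
score by the magnitude of the most negative eigenvalue; the response is the
maximum over scales, normalized to [0, 1] per slice. Bone and calcification
(HU above a threshold, dilated) are zeroed in the response before anything
else, and the accepted region must lie in an anterior-medial band relative
to a femoral-head template hit — the anatomical neighborhood in which the
common femoral artery runs.

On clinical data this stage is known to be the weakest link of the method
(small vessels, many confounders); it is retained as specified, with the
spatial prior and the bone threshold exposed in the configuration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.feature import hessian_matrix, hessian_matrix_eigvals

from .classify import RoiMeasurement, categorize
from .config import RunConfig
from .volume_io import Volume


@dataclass
class VesselnessMap:
    """Multiscale vesselness response of one slice.

    ``response`` is the per-pixel maximum over scales, normalized to [0, 1]
    (zero on the bone mask once the caller has applied it); ``per_scale``
    keeps the individual scale responses (same normalization) and
    ``scale_index`` the argmax scale per pixel, so that a detected
    structure can be measured at the scale that detected it.
    """

    response: np.ndarray
    scales_px: tuple[float, ...]
    per_scale: np.ndarray | None = None  # (n_scales, rows, cols)
    scale_index: np.ndarray | None = None


def vesselness2d(slice_2d: np.ndarray, scales_px: Sequence[float]) -> VesselnessMap:
    """Multiscale bright-structure vesselness of one slice.

    For each scale ``s`` the response is ``s**2 * (-lambda_2)`` wherever both
    eigenvalues of the scale-normalized Gaussian Hessian are non-positive
    (``lambda_2`` the more negative one), and 0 elsewhere. Requiring both
    eigenvalues non-positive restricts the response to the *interior* of
    bright blobs and ridges: outside a bright disc the radial second
    derivative turns positive in the smoothed tail, so the halo that a bare
    ``-lambda_2`` response would spread around every vessel is cut off and
    the half-peak ROI mask stays inside the lumen. The per-scale responses
    are maximized over scales and the map normalized to [0, 1] by its
    maximum; a constant slice maps to all zeros.
    """
    img = np.asarray(slice_2d, dtype=np.float64)
    stack = np.zeros((len(scales_px),) + img.shape)
    for i, s in enumerate(scales_px):
        H = hessian_matrix(
            img, sigma=float(s), mode="reflect", order="rc",
            use_gaussian_derivatives=True,
        )
        eig = hessian_matrix_eigvals(H)  # decreasing order: eig[0] >= eig[1]
        stack[i] = np.where((eig[1] < 0.0) & (eig[0] <= 0.0), float(s) ** 2 * -eig[1], 0.0)
    best = stack.max(axis=0)
    peak = float(best.max())
    # discretization noise on a (near-)flat slice is not signal
    floor = 1e-9 * max(1.0, float(np.ptp(img)))
    if peak > floor:
        best /= peak
        stack /= peak
    else:
        best[:] = 0.0
        stack[:] = 0.0
    return VesselnessMap(
        best, tuple(float(s) for s in scales_px), stack, stack.argmax(axis=0)
    )


def _passes_band(
    peak_rc: tuple[int, int],
    hits: Sequence[tuple[int, int]],
    mid_col: float,
    band_px: int,
    min_medial_px: int,
) -> bool:
    """Anterior-medial test: the peak must lie 0..band px anterior to a
    femoral-head hit and min..band px toward the midline."""
    pr, pc = peak_rc
    for hr, hc in hits:
        medial = 1.0 if hc < mid_col else -1.0
        d_ant = pr - hr
        d_med = (pc - hc) * medial
        if 0 <= d_ant <= band_px and min_medial_px <= d_med <= band_px:
            return True
    return False


def locate_femoral_roi(
    volume: Volume,
    soi3_index: int,
    femoral_head_hits: Sequence[tuple[int, int]],
    config: RunConfig | None = None,
) -> RoiMeasurement | None:
    """Place ROI 3 on the SOI-3 slice, or return ``None``.

    Pixels above the bone/calcification threshold (dilated) are excluded
    from the vesselness map; connected regions of the remaining response
    above ``min_response`` are candidates, restricted to the
    anterior-medial band of a femoral-head hit. Regions that touch the
    dilated bone mask are rejected as well: a response attached to cortical
    bone is trabecular or partial-volume structure, not a vessel lumen.
    The surviving region with the highest peak wins; its mask is the part
    of the region whose response *at the peak's winning scale* is above
    half the peak — measuring at the detected scale keeps the mask inside
    the lumen, where the max-over-scales map would bleed a large-scale halo
    past the vessel wall. Without femoral-head hits the ROI is skipped (the
    classifier then runs on two ROIs).
    """
    cfg = config or RunConfig()
    if not femoral_head_hits:
        return None
    slice_2d = volume.voxels[soi3_index]

    vmap = vesselness2d(slice_2d, cfg.vessel_scales_px(volume.spacing[0]))
    bone = slice_2d > cfg.bone_threshold_hu
    if cfg.bone_dilation_px > 0 and bone.any():
        bone = ndimage.binary_dilation(bone, iterations=cfg.bone_dilation_px)
    response = vmap.response.copy()
    response[bone] = 0.0
    renorm = float(response.max())
    per_scale = vmap.per_scale
    if renorm > 0:
        response /= renorm
        per_scale = per_scale / renorm

    labels, n_regions = ndimage.label(response > cfg.min_response)
    if n_regions == 0:
        return None
    bone_adjacent = ndimage.binary_dilation(bone) if bone.any() else bone
    mid_col = float(np.mean([h[1] for h in femoral_head_hits])) if len(
        femoral_head_hits
    ) > 1 else volume.slice_shape[1] / 2.0

    best_region, best_peak, best_pos = 0, 0.0, (0, 0)
    for region in range(1, n_regions + 1):
        region_mask = labels == region
        region_vals = np.where(region_mask, response, 0.0)
        pos = np.unravel_index(int(np.argmax(region_vals)), region_vals.shape)
        rpeak = float(region_vals[pos])
        if rpeak <= best_peak:
            continue
        if np.any(region_mask & bone_adjacent):
            continue
        if _passes_band(
            (int(pos[0]), int(pos[1])),
            femoral_head_hits,
            mid_col,
            cfg.search_band_px,
            cfg.search_band_min_medial_px,
        ):
            best_region, best_peak, best_pos = region, rpeak, (int(pos[0]), int(pos[1]))
    if best_region == 0:
        return None

    peak_scale = int(vmap.scale_index[best_pos])
    at_scale = per_scale[peak_scale]
    mask = (labels == best_region) & (at_scale >= at_scale[best_pos] / 2.0)
    values = slice_2d[mask]
    mean_hu = float(values.mean())
    pixels = np.argwhere(mask)
    return RoiMeasurement(
        roi_id=3,
        slice_index=soi3_index,
        mean_hu=mean_hu,
        n_pixels=int(values.size),
        category=categorize(mean_hu, cfg.category_boundaries),
        descriptor={
            "type": "pixels",
            "peak": [best_pos[0], best_pos[1]],
            "peak_response": round(best_peak, 4),
            "pixels": pixels.tolist(),
        },
    )
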