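"""Aortic ROI: Hough candidates, Eq-style step costs, DP path selection."""

import itertools
import math

import numpy as np
import pytest

from aortaqc import RunConfig, generate_phantom
from aortaqc.aorta import (
    CircleCandidate,
    CirclePath,
    hough_circles,
    measure_aortic_roi,
    select_aorta,
    step_cost,
)
from aortaqc.phantom import PhantomSpec, disc_mask


def brute_force_circle_search(slice_2d, radius_range, edge_threshold=100.0):
    """Independent oracle: for every center and radius, count edge pixels
    lying on the circle perimeter (|distance - r| <= 0.5), normalized by
    the circumference; return the argmax (row, col, radius)."""
    from aortaqc.aorta import _edge_pixels

    ys, xs, _, _ = _edge_pixels(slice_2d, edge_threshold)
    best = (-1.0, None)
    rows, cols = slice_2d.shape
    for r in range(radius_range[0], radius_range[1] + 1):
        for cr in range(rows):
            for cc in range(cols):
                d = np.hypot(ys - cr, xs - cc)
                score = np.count_nonzero(np.abs(d - r) <= 0.5) / (2 * math.pi * r)
                if score > best[0]:
                    best = (score, (cr, cc, r))
    return best[1]


def _disc_slice(shape, discs, background=40.0):
    sl = np.full(shape, background)
    for (r, c, rad, hu) in discs:
        sl[disc_mask(shape, (r, c), rad)] = hu
    return sl


# ---------------------------------------------------------------------------
# Hough transform


def test_hough_single_disc_matches_brute_force_oracle():
    sl = _disc_slice((64, 64), [(30, 40, 10, 300.0)])
    cands = hough_circles(sl, (8, 15))
    assert cands
    top = cands[0]
    oracle = brute_force_circle_search(sl, (8, 15))
    assert abs(top.row - oracle[0]) <= 1 and abs(top.col - oracle[1]) <= 1
    assert abs(top.radius - oracle[2]) <= 1
    # and both agree with the painted ground truth
    assert abs(top.row - 30) <= 1 and abs(top.col - 40) <= 1 and abs(top.radius - 10) <= 1


def test_hough_finds_both_discs():
    sl = _disc_slice((96, 96), [(30, 30, 10, 300.0), (60, 64, 12, 250.0)])
    cands = hough_circles(sl, (8, 15))
    found = {
        (round(c.row / 3), round(c.col / 3)) for c in cands
    }
    assert (10, 10) in found and (20, 21) in found


def test_hough_flat_slice_yields_no_candidates():
    assert hough_circles(np.full((64, 64), 123.0), (8, 15)) == []


def test_hough_scores_normalized_to_unit_interval():
    sl = _disc_slice((64, 64), [(30, 40, 10, 300.0)])
    for c in hough_circles(sl, (8, 15)):
        assert 0.0 <= c.accumulator_score <= 1.0


# ---------------------------------------------------------------------------
# step cost


def test_step_cost_zero_for_constant_disc_and_identical_circles():
    sl = np.full((64, 64), 270.0)
    cand = CircleCandidate(30, 30, 10, 0.5)
    assert step_cost(cand, cand, sl) == (0.0, 0.0, 0.0)


def test_step_cost_radius_and_distance_terms():
    sl = np.full((64, 64), 270.0)
    prev = CircleCandidate(30, 40, 10, 0.5)
    cur = CircleCandidate(33, 44, 12, 0.5)
    c_v, c_r, c_d = step_cost(prev, cur, sl)
    assert (c_v, c_r, c_d) == (0.0, 2.0, 5.0)


def test_step_cost_first_slice_has_no_pairwise_terms():
    sl = np.full((32, 32), 100.0)
    _, c_r, c_d = step_cost(None, CircleCandidate(16, 16, 8, 0.5), sl)
    assert c_r == 0.0 and c_d == 0.0


def test_step_cost_variance_matches_enumerated_mask():
    """Two-valued region: c_v equals the population variance of the pixels
    in the (1 px shrunk) disc divided by v0, computed by direct enumeration."""
    sl = np.full((64, 64), 200.0)
    sl[:, 32:] = 400.0
    cand = CircleCandidate(32, 32, 10, 0.5)
    c_v, _, _ = step_cost(None, cand, sl, v0=100.0)
    mask = disc_mask(sl.shape, (32, 32), 9)
    assert c_v == pytest.approx(np.var(sl[mask]) / 100.0)


def test_step_cost_disc_outside_slice_is_infinite():
    sl = np.full((32, 32), 100.0)
    c_v, c_r, c_d = step_cost(None, CircleCandidate(-50, -50, 5, 0.5), sl)
    assert math.isinf(c_v)


# ---------------------------------------------------------------------------
# path selection


def enumerate_all_paths(volume, soi_index, config):
    """Oracle: enumerate every candidate combination over the path slices
    and return the minimum total cost (and its circles)."""
    from aortaqc.aorta import hough_circles as hc

    r_range = config.radius_range_px(volume.spacing[0])
    layers = []
    for i in range(config.path_length):
        cands = hc(
            volume.voxels[soi_index + i], r_range, config.top_k, config.edge_threshold,
            config.hough_min_score,
        )
        if not cands:
            break
        layers.append(cands)
    best = (math.inf, None)
    for combo in itertools.product(*layers):
        total, prev = 0.0, None
        for i, cand in enumerate(combo):
            c_v, c_r, c_d = step_cost(prev, cand, volume.voxels[soi_index + i],
                                      config.variance_norm_v0)
            total += c_v + c_r + c_d
            prev = cand
        if total < best[0]:
            best = (total, combo)
    return best


def test_constant_tube_selected_with_near_zero_cost(clean_phantom, default_config):
    volume, gt = clean_phantom
    path = select_aorta(volume, gt.soi1, default_config)
    assert path is not None
    truth = gt.aorta_circles[gt.soi1]
    assert abs(path.circles[0].row - truth[0]) <= 1
    assert abs(path.circles[0].col - truth[1]) <= 1
    assert abs(path.circles[0].radius - truth[2]) <= 1
    # zero-noise constant-radius tube: only the tiny center drift costs
    assert path.total_cost < 10.0


def test_dp_equals_exhaustive_path_enumeration(default_config):
    for seed in (0, 1, 2):
        spec = PhantomSpec(noise_sigma_hu=10.0, seed=seed)
        volume, gt = generate_phantom(spec)
        path = select_aorta(volume, gt.soi1, default_config)
        best_cost, best_combo = enumerate_all_paths(volume, gt.soi1, default_config)
        assert path is not None
        assert path.total_cost == pytest.approx(best_cost)
        assert tuple(path.circles) == best_combo


def test_decoy_with_radius_jumps_never_beats_the_aorta(default_config):
    """A decoy whose radius alternates by 6 px between slices accumulates
    radius-difference cost; the steady aorta tube must win."""
    spec = PhantomSpec(noise_sigma_hu=0.0, vertebra=None)
    volume, gt = generate_phantom(spec)
    # paint an erratic decoy manually (alternating radius 8/14)
    for i in range(volume.n_slices):
        rad = 8 if i % 2 == 0 else 14
        volume.voxels[i][disc_mask(volume.slice_shape, (30.0, 96.0), rad)] = 350.0
    path = select_aorta(volume, gt.soi1, default_config)
    assert path is not None
    assert abs(path.circles[0].row - gt.aorta_circles[gt.soi1][0]) <= 1
    assert abs(path.circles[0].col - gt.aorta_circles[gt.soi1][1]) <= 1
    # the decoy path exists but is strictly costlier: check via enumeration
    best_cost, best_combo = enumerate_all_paths(volume, gt.soi1, default_config)
    assert path.total_cost == pytest.approx(best_cost)
    assert all(abs(c.col - 96) > 5 for c in best_combo)


def test_increasing_decoy_drift_never_lowers_its_cost(default_config):
    """Monotonicity: larger slice-to-slice center jumps of a decoy can only
    increase the cost of the best path through it."""
    costs = []
    for drift in (0, 3, 6, 9):
        spec = PhantomSpec(noise_sigma_hu=0.0, vertebra=None, bifurcation=None,
                           femoral=None, arteries=None, aorta=None)
        volume, _ = generate_phantom(spec)
        for i in range(20, 25):
            col = 64.0 + (drift if i % 2 else -drift) / 2.0
            volume.voxels[i][disc_mask(volume.slice_shape, (64.0, col), 10.0)] = 300.0
        path = select_aorta(volume, 20, default_config)
        assert path is not None
        costs.append(path.total_cost)
    assert costs == sorted(costs)


def test_structureless_stack_returns_none(default_config):
    spec = PhantomSpec(noise_sigma_hu=0.0, aorta=None, vertebra=None,
                       bifurcation=None, femoral=None, arteries=None)
    volume, _ = generate_phantom(spec)
    assert select_aorta(volume, 20, default_config) is None


def test_vanishing_circle_returns_none(default_config):
    """The only circular structure disappears after soi+1: fewer than three
    candidate layers exist, so no acceptable path remains."""
    spec = PhantomSpec(noise_sigma_hu=0.0, aorta=None, vertebra=None,
                       bifurcation=None, femoral=None, arteries=None)
    volume, _ = generate_phantom(spec)
    for i in (20, 21):
        volume.voxels[i][disc_mask(volume.slice_shape, (64.0, 64.0), 10.0)] = 300.0
    assert select_aorta(volume, 20, default_config) is None


def test_truncated_path_near_volume_end(default_config):
    """With only four slices left the path is truncated, flagged, and judged
    against a proportionally scaled threshold."""
    spec = PhantomSpec(noise_sigma_hu=0.0)
    spec.aorta.extent = (2, 96)
    volume, _ = generate_phantom(spec)
    path = select_aorta(volume, 92, default_config)
    assert path is not None
    assert path.truncated and len(path.circles) == 4


def test_selection_is_translation_equivariant(default_config):
    spec = PhantomSpec(noise_sigma_hu=0.0)
    volume, gt = generate_phantom(spec)
    path = select_aorta(volume, gt.soi1, default_config)
    dr, dc = 5, -7
    shifted = volume
    shifted.voxels[:] = np.roll(np.roll(volume.voxels, dr, axis=1), dc, axis=2)
    path_shifted = select_aorta(shifted, gt.soi1, default_config)
    assert path is not None and path_shifted is not None
    for a, b in zip(path.circles, path_shifted.circles):
        assert (b.row - a.row, b.col - a.col) == (dr, dc)
        assert b.radius == a.radius


# ---------------------------------------------------------------------------
# measurement


def test_radius_reduction_applied_with_floor():
    sl = np.full((64, 64), 300.0)
    volume_like = type("V", (), {})()
    from aortaqc.volume_io import Volume

    vol = Volume(np.stack([sl] * 3), (1.0, 1.0, 5.0))
    path = CirclePath(0, [CircleCandidate(32, 32, 10, 0.5)], [0.0], [0.0], [0.0])
    m = measure_aortic_roi(vol, path, 1, radius_reduction_px=4)
    assert m.descriptor["reduced_radius_px"] == 6
    assert m.mean_hu == 300.0 and m.category.value == "C"
    small = CirclePath(0, [CircleCandidate(32, 32, 3, 0.5)], [0.0], [0.0], [0.0])
    m2 = measure_aortic_roi(vol, small, 1, radius_reduction_px=4)
    assert m2.descriptor["reduced_radius_px"] == 1
    assert m2.n_pixels >= 1


def test_reduced_disc_excludes_calcified_ring(default_config):
    """A 2 px calcification ring at 1000 HU on the wall of a 270 HU lumen is
    excluded by the 4 px reduction: the Hough circle spans the ring, yet the
    measured mean stays within 5 HU of the lumen and equals the brute-force
    mean over the enumerated mask."""
    spec = PhantomSpec(noise_sigma_hu=0.0)
    spec.calcification.enabled = True
    volume, gt = generate_phantom(spec)
    truth = gt.aorta_circles[gt.soi1]
    r_range = default_config.radius_range_px(volume.spacing[0])
    cands = hough_circles(volume.voxels[gt.soi1], r_range,
                          edge_threshold=default_config.edge_threshold)
    circle = next(
        c for c in cands if abs(c.row - truth[0]) <= 1 and abs(c.col - truth[1]) <= 1
    )
    assert abs(circle.radius - truth[2]) <= 1  # detected radius spans the ring
    path = CirclePath(gt.soi1, [circle], [0.0], [0.0], [0.0])
    m = measure_aortic_roi(volume, path, 1, default_config.radius_reduction_px)
    assert abs(m.mean_hu - 270.0) <= 5.0
    mask = disc_mask(
        volume.slice_shape, (circle.row, circle.col), m.descriptor["reduced_radius_px"]
    )
    assert m.mean_hu == pytest.approx(volume.voxels[gt.soi1][mask].mean())
    assert m.n_pixels == int(mask.sum())
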