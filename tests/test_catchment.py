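"""Hill climbing, catchment extraction and the gradient-descent cross-check.

The brute-force oracle below is a literal scalar transcription of the
descending-gradient rule — (V1 − Vn)/distance > threshold over the 26
neighbourhood, steepest first, strict inequality, neighbours visited in the
documented (dz, dy, dx ascending) order — written independently of the
implementation it checks.
"""

import json
import math
import warnings

import numpy as np
import pytest

import catchvol as cv
from catchvol.catchment import (
    FALSE_MINIMUM,
    LEFT_VOLUME,
    SUBTHRESHOLD,
    SUCCESS,
    catchment_volume,
    gd_success_mask,
    gradient_descent,
    hill_climb,
    steepest_descending_neighbor,
    would_exit_volume,
)
from catchvol.idf import GridSpec, IDFVolume

from conftest import bowl_volume


# --- independent oracle ----------------------------------------------------


def oracle_climb(values, spacing, ref, start, threshold):
    """Brute-force hill climb: returns (path, status)."""
    shape = values.shape
    idx = tuple(start)
    path = [idx]
    while True:
        if idx == tuple(ref):
            return path, SUCCESS
        v1 = values[idx]
        best = None
        best_g = threshold
        any_desc = False
        exit_candidate = False
        for dz in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    if (dx, dy, dz) == (0, 0, 0):
                        continue
                    n = (idx[0] + dx, idx[1] + dy, idx[2] + dz)
                    dist = spacing * math.sqrt(dx * dx + dy * dy + dz * dz)
                    if all(0 <= n[a] < shape[a] for a in range(3)):
                        g = (v1 - values[n]) / dist
                        if g > 0:
                            any_desc = True
                        if g > best_g:
                            best_g = g
                            best = n
                    else:
                        m = (idx[0] - dx, idx[1] - dy, idx[2] - dz)
                        if all(0 <= m[a] < shape[a] for a in range(3)):
                            # extrapolated outside value 2*v1 - v_mirror
                            if (values[m] - v1) / dist > threshold:
                                exit_candidate = True
        if best is not None:
            idx = best
            path.append(idx)
            continue
        if exit_candidate:
            return path, LEFT_VOLUME
        if any_desc:
            return path, SUBTHRESHOLD
        return path, FALSE_MINIMUM


def random_volume(rng, shape, integers=False):
    vals = (
        rng.integers(0, 20, shape).astype(float)
        if integers
        else rng.uniform(0, 50, shape)
    )
    ref = tuple(int(rng.integers(0, s)) for s in shape)
    vals[ref] = -1.0  # ensure the reference is reachable in principle
    return IDFVolume(GridSpec((0, 0, 1), 0.2, shape), ref, vals)


# --- steepest neighbour ----------------------------------------------------


def test_uniform_volume_has_no_descending_neighbor():
    vol = IDFVolume(GridSpec((0, 0, 1), 0.1, (3, 3, 3)), (1, 1, 1), np.ones((3, 3, 3)))
    assert steepest_descending_neighbor(vol, (0, 0, 0), 0.0) is None


def test_bowl_neighbor_moves_closer_and_matches_exhaustive(bowl):
    ref = np.asarray(bowl.reference_index)
    for idx in [(0, 0, 0), (4, 4, 4), (0, 4, 2), (1, 1, 3)]:
        step = steepest_descending_neighbor(bowl, idx, 0.0)
        assert step is not None
        # exhaustive check: no neighbour has a steeper gradient
        v1 = bowl.values[idx]
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    n = (idx[0] + dx, idx[1] + dy, idx[2] + dz)
                    if n == idx or not bowl.grid.contains_index(n):
                        continue
                    d = bowl.grid.spacing * math.sqrt(dx * dx + dy * dy + dz * dz)
                    assert (v1 - bowl.values[n]) / d <= step.gradient + 1e-12
        assert np.linalg.norm(np.asarray(step.to_index) - ref) < np.linalg.norm(
            np.asarray(idx) - ref
        )


def test_threshold_above_max_slope_blocks_all(bowl):
    # steepest possible slope of the unit-distance bowl is 1 grey level per m
    for idx in [(0, 0, 0), (4, 2, 1), (3, 3, 3)]:
        if idx == bowl.reference_index:
            continue
        assert steepest_descending_neighbor(bowl, idx, 10.0) is None


# --- hill climbs -----------------------------------------------------------


def test_climb_from_reference_is_trivial_success(bowl):
    p = hill_climb(bowl, bowl.reference_index, 0.5)
    assert p.status == SUCCESS and len(p.indices) == 1


def test_bowl_all_starts_succeed_with_zero_threshold():
    vol = bowl_volume((3, 3, 3), ref=(1, 1, 1))
    for start in vol.grid.indices():
        assert hill_climb(vol, start, 0.0).status == SUCCESS


def test_plateau_shell_matches_enumeration_oracle():
    vol = bowl_volume((5, 5, 5), spacing=0.2, ref=(2, 2, 2))
    # flatten a shell at Chebyshev radius 2 to the shell's minimum value:
    # climbs that start on the plateau find no descending neighbour
    idx = np.stack(np.meshgrid(*(np.arange(5),) * 3, indexing="ij"), axis=-1)
    cheb = np.abs(idx - 2).max(axis=-1)
    vol.values[cheb == 2] = vol.values[cheb == 2].min()
    for start in vol.grid.indices():
        got = hill_climb(vol, start, 0.0)
        path, status = oracle_climb(vol.values, 0.2, (2, 2, 2), start, 0.0)
        assert got.status == status, start
        assert got.indices == path, start


def test_path_validity_strict_decrease_and_adjacency():
    rng = np.random.default_rng(12)
    for _ in range(20):
        vol = random_volume(rng, (4, 4, 4))
        for start in [(0, 0, 0), (3, 3, 3), (1, 2, 3)]:
            p = hill_climb(vol, start, 0.0)
            vals = [vol.values[i] for i in p.indices]
            assert all(a > b for a, b in zip(vals, vals[1:]))
            for a, b in zip(p.indices, p.indices[1:]):
                assert max(abs(x - y) for x, y in zip(a, b)) == 1
            assert len(set(p.indices)) == len(p.indices)


@pytest.mark.parametrize("integers", [False, True])
def test_hill_climb_matches_oracle_on_random_volumes(integers):
    rng = np.random.default_rng(99 if integers else 98)
    for _ in range(150):
        shape = tuple(int(rng.integers(2, 5)) for _ in range(3))
        vol = random_volume(rng, shape, integers=integers)
        threshold = float(rng.choice([0.0, 1.0, 5.0]))
        for start in vol.grid.indices():
            got = hill_climb(vol, start, threshold)
            path, status = oracle_climb(
                vol.values, vol.grid.spacing, vol.reference_index, start, threshold
            )
            assert got.status == status and got.indices == path


def test_boundary_exit_labelling():
    # values strictly decreasing toward +x: from the max-x face the descent
    # continues out of the grid
    grid = GridSpec((0, 0, 1), 0.2, (4, 4, 4))
    vals = -np.arange(4, dtype=float)[:, None, None] * np.ones((4, 4, 4))
    vol = IDFVolume(grid, (3, 1, 1), vals)
    assert would_exit_volume(vol, (3, 2, 2), 0.0)
    p = hill_climb(vol, (0, 2, 2), 0.0)
    assert p.status == LEFT_VOLUME and p.indices[-1][0] == 3


# --- catchment volumes -----------------------------------------------------


def test_uniform_idf_only_reference_succeeds():
    vol = IDFVolume(GridSpec((0, 0, 1), 0.1, (3, 3, 3)), (1, 1, 1), np.zeros((3, 3, 3)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        c = catchment_volume(vol, 0.0)
    assert c.success_count == 1 and c.status((1, 1, 1)) == SUCCESS


def test_bowl_catchment_full_success_and_monotone_threshold():
    vol = bowl_volume((5, 5, 5), spacing=1.0, ref=(2, 2, 2))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        c0 = catchment_volume(vol, 0.0)
    assert c0.success_count == 125 and c0.success_fraction == 1.0
    prev = 126
    for thr in (0.2, 0.5, 0.9, 1.5):
        c = catchment_volume(vol, thr)
        assert c.success_count <= prev
        prev = c.success_count
    assert prev < 125  # a threshold above the bowl slope prunes voxels


def test_monotone_threshold_on_random_volume():
    rng = np.random.default_rng(21)
    vol = random_volume(rng, (5, 5, 5))
    counts = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for thr in (0.0, 1.0, 3.0, 10.0, 50.0):
            counts.append(catchment_volume(vol, thr).success_count)
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_memoization_equivalence():
    rng = np.random.default_rng(31)
    for _ in range(10):
        vol = random_volume(rng, (5, 5, 5))
        thr = float(rng.choice([0.0, 2.0]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            memo = catchment_volume(vol, thr, memoize=True)
            plain = catchment_volume(vol, thr, memoize=False)
        assert np.array_equal(memo.status_codes, plain.status_codes)


def test_reference_voxel_and_success_set_definition(bowl):
    c = catchment_volume(bowl, 0.5, keep_paths=True)
    assert c.status(bowl.reference_index) == SUCCESS
    for start, path in c.paths.items():
        assert (path.indices[-1] == tuple(bowl.reference_index)) == (
            c.status(start) == SUCCESS
        )


def test_catchment_exports(tmp_path, bowl):
    c = catchment_volume(bowl, 0.5)
    c.to_ply(tmp_path / "c.ply")
    c.to_csv(tmp_path / "c.csv")
    c.summary_to_json(tmp_path / "c.json")
    ply = (tmp_path / "c.ply").read_text().splitlines()
    assert ply[0] == "ply" and f"element vertex {c.success_count}" in ply[2]
    n_pts = len(ply) - ply.index("end_header") - 1
    assert n_pts == c.success_count
    rows = (tmp_path / "c.csv").read_text().splitlines()
    assert len(rows) == 1 + bowl.values.size
    summary = json.loads((tmp_path / "c.json").read_text())
    assert summary["counts"]["success"] == c.success_count
    assert summary["threshold_grey_per_m"] == 0.5


# --- gradient descent ------------------------------------------------------


def test_gd_start_at_reference_immediate_success(bowl):
    tr = gradient_descent(bowl, bowl.grid.index_to_world(bowl.reference_index))
    assert tr.status == SUCCESS and len(tr.points) == 1


def test_gd_bowl_monotone_approach():
    vol = bowl_volume((7, 7, 7), spacing=0.5, ref=(3, 3, 3))
    ref_w = vol.grid.index_to_world((3, 3, 3))
    rng = np.random.default_rng(17)
    for _ in range(5):
        start = vol.grid.min_corner + rng.uniform(0.2, 2.8, 3)
        tr = gradient_descent(vol, start, step_m=0.1)
        assert tr.status == SUCCESS
        d = [np.linalg.norm(p - ref_w) for p in tr.points]
        assert all(a >= b - 1e-9 for a, b in zip(d, d[1:]))


def test_gd_parameter_validation(bowl):
    with pytest.raises(ValueError):
        gradient_descent(bowl, (0, 0, 1), step_m=-0.1)
    with pytest.raises(ValueError):
        gradient_descent(bowl, (0, 0, 1), stop_radius_m=0.0)
    with pytest.raises(ValueError, match="outside"):
        gradient_descent(bowl, (99.0, 0, 1))


def test_gd_success_mask_on_bowl():
    vol = bowl_volume((5, 5, 5), spacing=0.5, ref=(2, 2, 2))
    mask = gd_success_mask(vol)
    assert mask.all()
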