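"""Catchment volumes by thresholded steepest-gradient hill climbing.

From every grid point of a transIDF volume we follow the steepest descending
gradient between 26-connected neighbours,

    descending gradient = (V1 − Vn) / distance > 0,

where V1 is the r.m.s. difference at the current grid point, Vn at the
neighbour, and distance the Euclidean separation of the two points
(spacing·√d for a d-axis diagonal move).  A step is taken only when the
steepest gradient exceeds a per-metre threshold (by default 10% of the
reference image's maximum self-rotIDF per metre).  Grid points whose climb
reaches the reference location are successes; climbs that end in false
minima, stall below threshold, or would exit the sampled volume are
failures.  The set of success voxels is the catchment volume.

A continuous-space gradient-descent variant on the trilinearly interpolated
volume (no threshold) is provided as an independent cross-check that the
discrete climbs track a genuine continuous gradient.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .idf import IDFVolume

SUCCESS = "success"
FALSE_MINIMUM = "false_minimum"
SUBTHRESHOLD = "subthreshold"
LEFT_VOLUME = "left_volume"
STATUSES = (SUCCESS, FALSE_MINIMUM, SUBTHRESHOLD, LEFT_VOLUME)
_STATUS_CODE = {s: i for i, s in enumerate(STATUSES)}

# 26-neighbour offsets in fixed lexicographic (dz, dy, dx) order; ties among
# equal steepest gradients resolve to the first offset in this order.
NEIGHBOR_OFFSETS: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
)


@dataclass(frozen=True)
class GradientStep:
    """One accepted move of the hill climb."""

    from_index: tuple[int, int, int]
    to_index: tuple[int, int, int]
    distance: float  # metres
    gradient: float  # grey levels per metre, positive = descending


@dataclass
class ClimbPath:
    """Ordered grid indices visited by one climb, plus how it ended.

    IDF values strictly decrease along the path (which also rules out
    revisits), and consecutive indices are 26-neighbours.
    """

    indices: list[tuple[int, int, int]]
    status: str


def _offset_distances(spacing: float) -> np.ndarray:
    return spacing * np.sqrt(
        np.array([dx * dx + dy * dy + dz * dz for dx, dy, dz in NEIGHBOR_OFFSETS], float)
    )


def steepest_descending_neighbor(
    vol: IDFVolume, idx, threshold: float
) -> GradientStep | None:
    """Best supra-threshold descending neighbour of a grid point, or None.

    Examines the ≤26 in-grid neighbours and returns the one maximising
    (V1 − Vn)/distance, provided that maximum strictly exceeds the
    threshold (grey levels per metre).
    """
    idx = tuple(int(v) for v in idx)
    v1 = float(vol.values[idx])
    dists = _offset_distances(vol.grid.spacing)
    best: GradientStep | None = None
    for off, dist in zip(NEIGHBOR_OFFSETS, dists):
        n = (idx[0] + off[0], idx[1] + off[1], idx[2] + off[2])
        if not vol.grid.contains_index(n):
            continue
        g = (v1 - float(vol.values[n])) / dist
        if g > threshold and (best is None or g > best.gradient):
            best = GradientStep(idx, n, float(dist), g)
    return best


def has_descending_neighbor(vol: IDFVolume, idx) -> bool:
    """Whether any in-grid neighbour lies strictly below the current value."""
    return steepest_descending_neighbor(vol, idx, 0.0) is not None


def would_exit_volume(vol: IDFVolume, idx, threshold: float) -> bool:
    """One-sided boundary check: does a supra-threshold descent point out of
    the grid?

    For each out-of-grid neighbour direction the outside value is linearly
    extrapolated from the in-grid mirror point; the sampled climbs cannot
    literally leave the grid, so this is how boundary voxels earn the
    ``left_volume`` label.
    """
    idx = tuple(int(v) for v in idx)
    v1 = float(vol.values[idx])
    dists = _offset_distances(vol.grid.spacing)
    for off, dist in zip(NEIGHBOR_OFFSETS, dists):
        n = (idx[0] + off[0], idx[1] + off[1], idx[2] + off[2])
        if vol.grid.contains_index(n):
            continue
        m = (idx[0] - off[0], idx[1] - off[1], idx[2] - off[2])
        if not vol.grid.contains_index(m):
            continue
        # extrapolated outside value: V_out = 2·V1 − V_mirror
        g = (float(vol.values[m]) - v1) / dist
        if g > threshold:
            return True
    return False


def _classify_terminal(vol: IDFVolume, idx, threshold: float) -> str:
    if idx == tuple(vol.reference_index):
        return SUCCESS
    if would_exit_volume(vol, idx, threshold):
        return LEFT_VOLUME
    if has_descending_neighbor(vol, idx):
        return SUBTHRESHOLD
    return FALSE_MINIMUM


def hill_climb(vol: IDFVolume, start, threshold: float) -> ClimbPath:
    """Iterated steepest-gradient climbing from one grid point.

    Terminates at the reference (``success``), at a local minimum
    (``false_minimum``), where every descending gradient is at or below the
    threshold (``subthreshold``), or where the only supra-threshold descent
    points out of the grid (``left_volume``).  Strict decrease on a finite
    grid guarantees termination.
    """
    idx = tuple(int(v) for v in start)
    if not vol.grid.contains_index(idx):
        raise ValueError(f"start {idx} outside grid")
    path = [idx]
    while True:
        if idx == tuple(vol.reference_index):
            return ClimbPath(path, SUCCESS)
        step = steepest_descending_neighbor(vol, idx, threshold)
        if step is None:
            return ClimbPath(path, _classify_terminal(vol, idx, threshold))
        idx = step.to_index
        path.append(idx)


@dataclass
class CatchmentVolume:
    """Per-voxel climb outcome over a transIDF volume.

    The success set — every start voxel whose climb reaches the reference —
    is the catchment volume.
    """

    grid: "GridSpec"
    reference_index: tuple[int, int, int]
    status_codes: np.ndarray  # int8, indexes into STATUSES
    threshold: float
    paths: dict[tuple[int, int, int], ClimbPath] | None = None

    @property
    def success_mask(self) -> np.ndarray:
        return self.status_codes == _STATUS_CODE[SUCCESS]

    @property
    def success_count(self) -> int:
        return int(self.success_mask.sum())

    @property
    def success_fraction(self) -> float:
        return self.success_count / self.status_codes.size

    def status(self, idx) -> str:
        return STATUSES[int(self.status_codes[tuple(idx)])]

    def counts(self) -> dict[str, int]:
        return {
            s: int((self.status_codes == c).sum()) for s, c in _STATUS_CODE.items()
        }

    # -- exports ------------------------------------------------------------

    def success_points(self) -> np.ndarray:
        """World coordinates (N, 3) of the catchment voxels."""
        idx = np.argwhere(self.success_mask)
        return self.grid.min_corner + idx * self.grid.spacing

    def to_ply(self, path) -> None:
        """ASCII PLY point cloud of the success voxels (for 3D viewers)."""
        pts = self.success_points()
        with open(path, "w") as fh:
            fh.write(
                "ply\nformat ascii 1.0\n"
                f"element vertex {len(pts)}\n"
                "property float x\nproperty float y\nproperty float z\n"
                "end_header\n"
            )
            for x, y, z in pts:
                fh.write(f"{x:.6g} {y:.6g} {z:.6g}\n")

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("i,j,k,x_m,y_m,z_m,status\n")
            for idx in np.ndindex(*self.status_codes.shape):
                x, y, z = self.grid.index_to_world(idx)
                fh.write(
                    f"{idx[0]},{idx[1]},{idx[2]},{x:.6g},{y:.6g},{z:.6g},"
                    f"{self.status(idx)}\n"
                )

    def summary(self) -> dict:
        return {
            "threshold_grey_per_m": self.threshold,
            "reference_index": list(self.reference_index),
            "n_voxels": int(self.status_codes.size),
            "counts": self.counts(),
            "success_fraction": self.success_fraction,
        }

    def summary_to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def catchment_volume(
    vol: IDFVolume,
    threshold: float,
    memoize: bool = True,
    keep_paths: bool = False,
) -> CatchmentVolume:
    """Run a hill climb from every grid point and label each voxel.

    With ``memoize`` (default) a climb that merges into an already
    classified path inherits that path's terminal status — equivalent to the
    unmemoized computation because climbs are deterministic functions of the
    current voxel.
    """
    if threshold == 0.0:
        import warnings

        warnings.warn(
            "catchment with threshold 0: unthresholded hill climbing",
            RuntimeWarning,
            stacklevel=2,
        )
    codes = np.full(vol.grid.counts, -1, dtype=np.int8)
    paths: dict[tuple[int, int, int], ClimbPath] = {}
    for start in vol.grid.indices():
        if memoize and codes[start] >= 0 and not keep_paths:
            continue
        if keep_paths or not memoize:
            p = hill_climb(vol, start, threshold)
            codes[start] = _STATUS_CODE[p.status]
            if keep_paths:
                paths[start] = p
            continue
        # memoized walk: stop as soon as we merge into a classified voxel
        idx = start
        visited = [idx]
        while True:
            if codes[idx] >= 0:
                terminal = int(codes[idx])
                break
            if idx == tuple(vol.reference_index):
                terminal = _STATUS_CODE[SUCCESS]
                break
            step = steepest_descending_neighbor(vol, idx, threshold)
            if step is None:
                terminal = _STATUS_CODE[_classify_terminal(vol, idx, threshold)]
                break
            idx = step.to_index
            visited.append(idx)
        for v in visited:
            codes[v] = terminal
    return CatchmentVolume(
        vol.grid,
        tuple(vol.reference_index),
        codes,
        threshold,
        paths if keep_paths else None,
    )


# ---------------------------------------------------------------------------
# continuous gradient descent (cross-check)
# ---------------------------------------------------------------------------


@dataclass
class DescentTrace:
    """Continuous-space descent trace: visited points and how it ended."""

    points: list[np.ndarray] = field(default_factory=list)
    status: str = FALSE_MINIMUM


def gradient_descent(
    vol: IDFVolume,
    start,
    step_m: float | None = None,
    stop_radius_m: float | None = None,
    max_steps: int | None = None,
    grad_tol: float = 1e-9,
) -> DescentTrace:
    """Fixed-step steepest descent on the trilinearly interpolated volume.

    No threshold is applied.  Succeeds on coming within ``stop_radius_m``
    (default: one grid spacing) of the reference location; fails on leaving
    the grid hull (``left_volume``) or on a vanishing gradient away from the
    reference (``false_minimum``).
    """
    g = vol.grid
    step_m = g.spacing / 2.0 if step_m is None else step_m
    stop_radius_m = g.spacing if stop_radius_m is None else stop_radius_m
    if step_m <= 0 or stop_radius_m <= 0:
        raise ValueError("step_m and stop_radius_m must be > 0")
    lo, hi = g.min_corner, g.index_to_world(np.asarray(g.counts) - 1)
    interp = RegularGridInterpolator(
        tuple(g.axis_coords(a) for a in range(3)), vol.values
    )
    ref = g.index_to_world(vol.reference_index)
    pos = np.asarray(start, dtype=np.float64).copy()
    if np.any(pos < lo) or np.any(pos > hi):
        raise ValueError(f"start {pos} outside the grid hull")
    if max_steps is None:
        max_steps = int(20 * np.linalg.norm(hi - lo) / step_m) + 10
    h = g.spacing / 2.0

    def grad(p: np.ndarray) -> np.ndarray:
        out = np.zeros(3)
        for a in range(3):
            pp, pm = p.copy(), p.copy()
            pp[a] = min(p[a] + h, hi[a])
            pm[a] = max(p[a] - h, lo[a])
            if pp[a] == pm[a]:
                continue
            out[a] = (interp(pp)[0] - interp(pm)[0]) / (pp[a] - pm[a])
        return out

    trace = DescentTrace(points=[pos.copy()])
    for _ in range(max_steps):
        if np.linalg.norm(pos - ref) <= stop_radius_m:
            trace.status = SUCCESS
            return trace
        gv = grad(pos)
        gn = np.linalg.norm(gv)
        if gn < grad_tol:
            trace.status = FALSE_MINIMUM
            return trace
        pos = pos - step_m * gv / gn
        trace.points.append(pos.copy())
        if np.any(pos < lo) or np.any(pos > hi):
            trace.status = LEFT_VOLUME
            return trace
    trace.status = FALSE_MINIMUM
    return trace


def gd_success_mask(
    vol: IDFVolume,
    step_m: float | None = None,
    stop_radius_m: float | None = None,
) -> np.ndarray:
    """Boolean grid of voxels whose continuous descent reaches the reference.

    Runs :func:`gradient_descent` from every voxel centre; used to quantify
    agreement with thresholdless hill climbing.
    """
    out = np.zeros(vol.grid.counts, dtype=bool)
    for idx in vol.grid.indices():
        tr = gradient_descent(vol, vol.grid.index_to_world(idx), step_m, stop_radius_m)
        out[idx] = tr.status == SUCCESS
    return out
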