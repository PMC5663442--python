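"""Image difference functions over 3D sampling grids.

The navigational information carried by a panoramic snapshot is quantified
by root-mean-square pixel differences between the snapshot (the reference)
and views elsewhere:

* the **rotIDF** compares the reference, rotated about the vertical axis in
  one-column steps, with a view at the same place — its minimum gives the
  best-matching heading, and its self-comparison maximum sets the gradient
  detection threshold used for catchment extraction;
* the **transIDF** compares same-orientation views on a regular 3D grid
  with the reference — a 3D scalar field that grows smoothly away from the
  reference location and whose basin of attraction is the catchment volume.

All r.m.s. values are in grey levels on the 0–255 scale (maximum possible
difference 255), computed in double precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import h5py
import numpy as np

from .panorama import RenderSettings, horizon_mask, render_panorama, roll_azimuth
from .scene import Scene


# ---------------------------------------------------------------------------
# sampling grids
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GridSpec:
    """Regular 3D sampling lattice, axis-aligned (x east, y north, z up).

    Index (0, 0, 0) sits at the minimum corner; index (i, j, k) maps to
    ``min_corner + spacing * (i, j, k)``.
    """

    center: tuple[float, float, float]
    spacing: float
    counts: tuple[int, int, int]

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        if any(c < 1 for c in self.counts):
            raise ValueError("counts must all be >= 1")

    @classmethod
    def from_side(
        cls, side_m: float, spacing_m: float, center=(0.0, 0.0, 0.0)
    ) -> "GridSpec":
        """Cube grid inclusive of both boundary planes: round(side/spacing)+1
        samples per axis (5 m at 0.1 m spacing → 51)."""
        n = int(round(side_m / spacing_m)) + 1
        return cls(tuple(float(c) for c in center), float(spacing_m), (n, n, n))

    @property
    def min_corner(self) -> np.ndarray:
        c = np.asarray(self.center, dtype=np.float64)
        n = np.asarray(self.counts, dtype=np.float64)
        return c - (n - 1) / 2.0 * self.spacing

    def index_to_world(self, idx) -> np.ndarray:
        idx = np.asarray(idx, dtype=np.float64)
        return self.min_corner + idx * self.spacing

    def world_to_index(self, pos) -> tuple[int, int, int]:
        rel = (np.asarray(pos, dtype=np.float64) - self.min_corner) / self.spacing
        idx = np.rint(rel).astype(int)
        if not np.allclose(rel, idx, atol=1e-6):
            raise ValueError(f"position {pos} is not on the grid")
        return tuple(int(v) for v in idx)

    def contains_index(self, idx) -> bool:
        return all(0 <= idx[a] < self.counts[a] for a in range(3))

    def axis_coords(self, axis: int) -> np.ndarray:
        return self.min_corner[axis] + self.spacing * np.arange(self.counts[axis])

    @property
    def n_points(self) -> int:
        return int(np.prod(self.counts))

    def indices(self):
        """Iterate all (i, j, k) indices in C order."""
        nx, ny, nz = self.counts
        for i in range(nx):
            for j in range(ny):
                for k in range(nz):
                    yield (i, j, k)


# ---------------------------------------------------------------------------
# r.m.s. differences and rotIDF
# ---------------------------------------------------------------------------


def solid_angle_weights(shape: tuple[int, int]) -> np.ndarray:
    """Per-pixel solid-angle weights for an equirectangular raster.

    Proportional to cos(elevation) of each row, so the oversampled polar
    rows count less. Off by default everywhere: the standard r.m.s. is
    unweighted over raw pixels.
    """
    h, w = shape
    el = np.radians(90.0 - (np.arange(h) + 0.5) * 180.0 / h)
    return np.broadcast_to(np.cos(el)[:, None], (h, w)).copy()


def rms_difference(
    a: np.ndarray,
    b: np.ndarray,
    mask: np.ndarray | None = None,
    weights: np.ndarray | None = None,
) -> float:
    """Root-mean-square pixel difference between two greyscale rasters,
    over the masked pixels (grey levels, 0–255 scale).

    ``weights`` (optional, e.g. :func:`solid_angle_weights`) turns the mean
    into a weighted mean.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    d2 = (a - b) ** 2
    if weights is not None:
        if weights.shape != a.shape:
            raise ValueError("weights shape must match the images")
    if mask is not None:
        if mask.shape != a.shape:
            raise ValueError("mask shape must match the images")
        if not mask.any():
            raise ValueError("mask selects no pixels")
        d2 = d2[mask]
        if weights is not None:
            weights = weights[mask]
    if weights is None:
        return float(np.sqrt(d2.mean()))
    return float(np.sqrt(np.average(d2, weights=weights)))


def _check_row_uniform(mask: np.ndarray) -> None:
    if not np.all(mask == mask[:, :1]):
        raise ValueError(
            "rotIDF masks must keep or drop whole rows (azimuth-uniform), "
            "otherwise rolling would change the masked pixel set"
        )


def rot_idf(
    reference: np.ndarray, current: np.ndarray, mask: np.ndarray | None = None
) -> np.ndarray:
    """Rotational image difference function (one value per column shift).

    Entry k is the r.m.s. difference between the reference rolled by k
    columns and the comparison view; one shift step = 360/W degrees.
    """
    reference = np.asarray(reference)
    current = np.asarray(current)
    if reference.shape != current.shape:
        raise ValueError("reference and current must share a shape")
    if mask is not None:
        _check_row_uniform(np.asarray(mask))
    w = reference.shape[1]
    return np.array(
        [rms_difference(roll_azimuth(reference, k), current, mask) for k in range(w)]
    )


def max_self_rot_idf(reference: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Maximum of the rotIDF of the reference rotated against itself.

    Zero only for images constant along every unmasked row; callers treat a
    zero as a degenerate threshold.
    """
    return float(rot_idf(reference, reference, mask).max())


def gradient_threshold(
    reference: np.ndarray, mask: np.ndarray | None = None, fraction: float = 0.10
) -> float:
    """Per-metre gradient acceptance threshold (grey levels / m).

    Defined as ``fraction`` (default 10%) of the maximum self-rotIDF of the
    reference, providing a relative measure that accounts for local image
    structure.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    m = max_self_rot_idf(reference, mask)
    if m == 0.0:
        warnings.warn(
            "degenerate gradient threshold 0 (constant reference image); "
            "catchment extraction reduces to unthresholded hill climbing",
            RuntimeWarning,
            stacklevel=2,
        )
    return fraction * m


# ---------------------------------------------------------------------------
# grid rendering and the transIDF volume
# ---------------------------------------------------------------------------


def render_grid_stack(
    scene: Scene,
    grid: GridSpec,
    settings: RenderSettings | None = None,
    cache_path=None,
    progress: bool = False,
) -> np.ndarray:
    """Greyscale panoramas at every grid point: (nx, ny, nz, H, W) uint8.

    With ``cache_path`` the stack is stored to (or reloaded from) HDF5 so
    that transIDFs for several reference choices reuse one set of renders.
    """
    settings = settings or RenderSettings()
    if cache_path is not None:
        try:
            stack, cached_grid = load_stack(cache_path)
            if cached_grid == grid and stack.shape[3] == settings.pano_height:
                return stack
        except (FileNotFoundError, OSError):
            pass
    nx, ny, nz = grid.counts
    stack = np.empty((nx, ny, nz, settings.pano_height, settings.pano_width), dtype=np.uint8)
    it = grid.indices()
    if progress:
        from tqdm import tqdm

        it = tqdm(list(it), desc="rendering grid", unit="pano")
    for idx in it:
        stack[idx] = render_panorama(scene, grid.index_to_world(idx), settings)
    if cache_path is not None:
        save_stack(cache_path, stack, grid)
    return stack


def save_stack(path, stack: np.ndarray, grid: GridSpec) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("panoramas", data=stack, compression="gzip", compression_opts=1)
        d.attrs["center"] = np.asarray(grid.center)
        d.attrs["spacing"] = grid.spacing
        d.attrs["counts"] = np.asarray(grid.counts)


def load_stack(path) -> tuple[np.ndarray, GridSpec]:
    with h5py.File(path, "r") as f:
        d = f["panoramas"]
        grid = GridSpec(
            tuple(float(v) for v in d.attrs["center"]),
            float(d.attrs["spacing"]),
            tuple(int(v) for v in d.attrs["counts"]),
        )
        return d[...], grid


@dataclass
class IDFVolume:
    """Translational image difference function over a 3D grid.

    ``values[i, j, k]`` is the r.m.s. difference (grey levels) between the
    reference panorama and the same-orientation view at grid index
    (i, j, k); zero at the reference index when the reference was rendered
    there with the same mask.
    """

    grid: GridSpec
    reference_index: tuple[int, int, int]
    values: np.ndarray
    mask_mode: str = "all"

    def __post_init__(self):
        if tuple(self.values.shape) != tuple(self.grid.counts):
            raise ValueError("values shape must equal grid counts")
        if not self.grid.contains_index(self.reference_index):
            raise ValueError(f"reference_index {self.reference_index} outside grid")

    # -- extraction helpers -------------------------------------------------

    def transect(self, axis: str, **fixed) -> tuple[np.ndarray, np.ndarray]:
        """Axis-parallel line of values, e.g. ``transect('z', i=5, j=5)``.

        Returns (world coordinates along the axis, values).
        """
        ax = "xyz".index(axis)
        others = [a for a in range(3) if a != ax]
        names = ["i", "j", "k"]
        sel: list = [slice(None)] * 3
        for a in others:
            sel[a] = int(fixed[names[a]])
        return self.grid.axis_coords(ax), self.values[tuple(sel)]

    def slice(self, axis: str, index: int) -> np.ndarray:
        ax = "xyz".index(axis)
        sel: list = [slice(None)] * 3
        sel[ax] = index
        return self.values[tuple(sel)]

    def transect_to_csv(self, path, axis: str, **fixed) -> None:
        coords, vals = self.transect(axis, **fixed)
        np.savetxt(
            path,
            np.column_stack([coords, vals]),
            delimiter=",",
            header=f"{axis}_m,rms_grey",
            comments="",
        )

    def slice_to_csv(self, path, axis: str, index: int) -> None:
        np.savetxt(path, self.slice(axis, index), delimiter=",")

    # -- HDF5 ---------------------------------------------------------------

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            d = f.create_dataset("idf", data=self.values)
            d.attrs["center"] = np.asarray(self.grid.center)
            d.attrs["spacing"] = self.grid.spacing
            d.attrs["counts"] = np.asarray(self.grid.counts)
            d.attrs["reference_index"] = np.asarray(self.reference_index)
            d.attrs["mask_mode"] = self.mask_mode

    @classmethod
    def load(cls, path) -> "IDFVolume":
        with h5py.File(path, "r") as f:
            d = f["idf"]
            grid = GridSpec(
                tuple(float(v) for v in d.attrs["center"]),
                float(d.attrs["spacing"]),
                tuple(int(v) for v in d.attrs["counts"]),
            )
            return cls(
                grid,
                tuple(int(v) for v in d.attrs["reference_index"]),
                d[...],
                str(d.attrs["mask_mode"]),
            )


def trans_idf_from_stack(
    stack: np.ndarray,
    grid: GridSpec,
    reference_index: tuple[int, int, int],
    mask_mode: str = "all",
    reference: np.ndarray | None = None,
) -> IDFVolume:
    """transIDF from a pre-rendered panorama stack.

    The reference defaults to the stack's own panorama at
    ``reference_index`` (so the value there is exactly zero).
    """
    if not grid.contains_index(reference_index):
        raise ValueError(f"reference_index {reference_index} outside grid")
    ref = stack[tuple(reference_index)] if reference is None else reference
    mask = horizon_mask(mask_mode, ref.shape[-2:])
    flat = stack.reshape(-1, *stack.shape[-2:])
    ref_m = np.asarray(ref, dtype=np.float64)[mask]
    vals = np.empty(flat.shape[0], dtype=np.float64)
    chunk = max(1, (1 << 26) // max(ref_m.size, 1))  # ~0.5 GB of float64 per chunk
    for s in range(0, flat.shape[0], chunk):
        block = flat[s : s + chunk][:, mask].astype(np.float64)
        vals[s : s + chunk] = np.sqrt(((block - ref_m) ** 2).mean(axis=1))
    return IDFVolume(grid, tuple(reference_index), vals.reshape(stack.shape[:3]), mask_mode)


def trans_idf_volume(
    scene: Scene,
    grid: GridSpec,
    reference_index: tuple[int, int, int],
    mask_mode: str = "all",
    settings: RenderSettings | None = None,
    stack: np.ndarray | None = None,
    cache_path=None,
    progress: bool = False,
) -> IDFVolume:
    """Render (or reuse) the grid stack and compute the transIDF volume
    against the reference panorama at ``reference_index``.

    All panoramas share the grid-aligned orientation, so the differences are
    due to translation only.
    """
    if stack is None:
        stack = render_grid_stack(scene, grid, settings, cache_path, progress)
    return trans_idf_from_stack(stack, grid, reference_index, mask_mode)
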