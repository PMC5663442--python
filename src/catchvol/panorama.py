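"""Cube-map rendering and equirectangular panorama projection.

Views are rendered as six square perspective images (north, east, south,
west, up, down) with 95°×95° fields of view, then spherically projected onto
a single equirectangular raster.  At the reference resolution the faces are
128×128 and the panorama 384×192, i.e. 360/384 = 0.9375° per pixel; a
``scale`` on :class:`RenderSettings` shrinks both consistently for
desk-scale experiments.

Conventions (fixed throughout the package):

* world axes: x = east, y = north, z = up;
* azimuth: 0° = north, increasing clockwise through east (compass);
  column c of a panorama is centred on azimuth (c + 0.5) · 360/W;
* elevation: row r is centred on 90° − (r + 0.5) · 180/H, so the horizon
  lies exactly on the boundary between rows H/2 − 1 and H/2;
* greyscale: ITU-R BT.601 luma (0.299 R + 0.587 G + 0.114 B), rounded.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .scene import Scene

FACE_NAMES = ("north", "east", "south", "west", "up", "down")

# forward, right, up basis per face (row 0 of a face raster points along +up,
# column 0 along -right)
_FACE_BASES: dict[str, tuple[tuple, tuple, tuple]] = {
    "north": ((0, 1, 0), (1, 0, 0), (0, 0, 1)),
    "east": ((1, 0, 0), (0, -1, 0), (0, 0, 1)),
    "south": ((0, -1, 0), (-1, 0, 0), (0, 0, 1)),
    "west": ((-1, 0, 0), (0, 1, 0), (0, 0, 1)),
    "up": ((0, 0, 1), (1, 0, 0), (0, 1, 0)),
    "down": ((0, 0, -1), (1, 0, 0), (0, -1, 0)),
}


@dataclass
class RenderSettings:
    """Resolution and sampling knobs for the rendering pipeline.

    ``face_res=128`` with ``pano_width=384`` is the reference configuration;
    both can be reduced proportionally for quick experiments.
    """

    face_res: int = 128
    pano_width: int = 384
    fov_deg: float = 95.0
    sampling: str = "bilinear"  # or "nearest" for bit-exactness checks

    @property
    def pano_height(self) -> int:
        return self.pano_width // 2

    def __post_init__(self):
        if self.pano_width % 2:
            raise ValueError("pano_width must be even")
        if self.sampling not in ("bilinear", "nearest"):
            raise ValueError("sampling must be 'bilinear' or 'nearest'")


@dataclass
class CubeFaceSet:
    """Six 95°-FOV face rasters sharing one position and the grid-aligned
    orientation (x east, y north, z up)."""

    faces: dict[str, np.ndarray]  # name -> (res, res, 3) float in [0, 255]
    position: np.ndarray
    fov_deg: float = 95.0

    @property
    def res(self) -> int:
        return self.faces["north"].shape[0]


def face_ray_directions(face: str, res: int, fov_deg: float = 95.0) -> np.ndarray:
    """Unit view directions (res, res, 3) of every pixel of one cube face."""
    f, r, u = (np.asarray(v, dtype=np.float64) for v in _FACE_BASES[face])
    th = math.tan(math.radians(fov_deg) / 2.0)
    ndc = (np.arange(res) + 0.5) * 2.0 / res - 1.0
    x = ndc[None, :] * th  # along +right, left to right
    y = -ndc[:, None] * th  # along +up, top row first
    d = f[None, None, :] + x[..., None] * r + (y[..., None] * u)
    return d / np.linalg.norm(d, axis=-1, keepdims=True)


def render_cubemap(
    scene: Scene,
    position,
    settings: RenderSettings | None = None,
    allow_below_ground: bool = False,
) -> CubeFaceSet:
    """Render the six-camera cube-map at a position (metres).

    One ray trace per pixel; raises if the camera is at or below the ground
    plane unless ``allow_below_ground``.
    """
    settings = settings or RenderSettings()
    pos = np.asarray(position, dtype=np.float64)
    if pos[2] <= 0 and not allow_below_ground:
        raise ValueError(f"camera position z={pos[2]} is not above ground")
    res = settings.face_res
    faces = {}
    for name in FACE_NAMES:
        dirs = face_ray_directions(name, res, settings.fov_deg).reshape(-1, 3)
        colors = scene.trace(np.broadcast_to(pos, dirs.shape), dirs)
        faces[name] = colors.reshape(res, res, 3)
    return CubeFaceSet(faces=faces, position=pos, fov_deg=settings.fov_deg)


def panorama_directions(width: int) -> np.ndarray:
    """Unit view directions (H, W, 3) of the equirectangular pixel centres."""
    height = width // 2
    az = np.radians((np.arange(width) + 0.5) * 360.0 / width)
    el = np.radians(90.0 - (np.arange(height) + 0.5) * 180.0 / height)
    saz, caz = np.sin(az)[None, :], np.cos(az)[None, :]
    sel_, cel = np.sin(el)[:, None], np.cos(el)[:, None]
    return np.stack(
        [saz * cel, caz * cel, np.broadcast_to(sel_, (height, width))], axis=-1
    )


def _dominant_face(d: np.ndarray) -> np.ndarray:
    """Index into FACE_NAMES of the face whose axis dominates each direction."""
    ax = np.argmax(np.abs(d), axis=-1)  # 0=x, 1=y, 2=z
    pos = np.take_along_axis(d, ax[..., None], axis=-1)[..., 0] >= 0
    out = np.empty(d.shape[:-1], dtype=np.intp)
    out[(ax == 1) & pos] = 0  # north
    out[(ax == 0) & pos] = 1  # east
    out[(ax == 1) & ~pos] = 2  # south
    out[(ax == 0) & ~pos] = 3  # west
    out[(ax == 2) & pos] = 4  # up
    out[(ax == 2) & ~pos] = 5  # down
    return out


def cubemap_to_equirect(
    faces: CubeFaceSet, width: int = 384, sampling: str = "bilinear"
) -> np.ndarray:
    """Spherically project a cube-map to an equirectangular RGB raster.

    Each output pixel selects the face with the dominant direction component
    (the 95° FOV guarantees the sample falls inside that face) and samples it
    bilinearly (or nearest-neighbour when ``sampling='nearest'``).
    Returns (H, W, 3) float in [0, 255] with H = width // 2.
    """
    res = faces.res
    th = math.tan(math.radians(faces.fov_deg) / 2.0)
    d = panorama_directions(width)
    face_idx = _dominant_face(d)
    out = np.empty(d.shape[:-1] + (3,), dtype=np.float64)
    for k, name in enumerate(FACE_NAMES):
        sel = face_idx == k
        if not sel.any():
            continue
        f, r, u = (np.asarray(v, dtype=np.float64) for v in _FACE_BASES[name])
        ds = d[sel]
        denom = ds @ f
        a = (ds @ r) / denom
        b = (ds @ u) / denom
        col = (a / th + 1.0) * res / 2.0 - 0.5
        row = (1.0 - b / th) * res / 2.0 - 0.5
        img = faces.faces[name]
        if sampling == "nearest":
            ci = np.clip(np.rint(col).astype(int), 0, res - 1)
            ri = np.clip(np.rint(row).astype(int), 0, res - 1)
            out[sel] = img[ri, ci]
        else:
            c0 = np.clip(np.floor(col).astype(int), 0, res - 1)
            r0 = np.clip(np.floor(row).astype(int), 0, res - 1)
            c1 = np.minimum(c0 + 1, res - 1)
            r1 = np.minimum(r0 + 1, res - 1)
            tc = np.clip(col - c0, 0.0, 1.0)[:, None]
            tr = np.clip(row - r0, 0.0, 1.0)[:, None]
            out[sel] = (
                img[r0, c0] * (1 - tc) * (1 - tr)
                + img[r0, c1] * tc * (1 - tr)
                + img[r1, c0] * (1 - tc) * tr
                + img[r1, c1] * tc * tr
            )
    return out


def to_grayscale(p: np.ndarray) -> np.ndarray:
    """Flatten an RGB raster to 8-bit greyscale (BT.601 luma, rounded).

    Already-grey input (2-D array) is returned unchanged.
    """
    p = np.asarray(p)
    if p.ndim == 2:
        return p
    y = 0.299 * p[..., 0] + 0.587 * p[..., 1] + 0.114 * p[..., 2]
    return np.clip(np.rint(y), 0, 255).astype(np.uint8)


def roll_azimuth(p: np.ndarray, k: int) -> np.ndarray:
    """Circularly shift panorama columns by k (one column = 360/W degrees,
    positive shifts move content clockwise in azimuth)."""
    return np.roll(p, int(k), axis=1)


def horizon_mask(keep: str, shape: tuple[int, int] = (192, 384)) -> np.ndarray:
    """Boolean mask over a panorama raster.

    ``above`` keeps the positive-elevation half (rows 0 .. H/2−1), ``below``
    the rest, ``all`` everything.
    """
    if keep not in ("above", "below", "all"):
        raise ValueError(f"keep must be 'above', 'below' or 'all', got {keep!r}")
    h, w = shape
    m = np.zeros((h, w), dtype=bool)
    if keep == "all":
        m[:] = True
    elif keep == "above":
        m[: h // 2] = True
    else:
        m[h // 2 :] = True
    return m


def render_panorama(
    scene: Scene,
    position,
    settings: RenderSettings | None = None,
    grayscale: bool = True,
) -> np.ndarray:
    """Cube-map → equirectangular → (optional) greyscale, in one call."""
    settings = settings or RenderSettings()
    faces = render_cubemap(scene, position, settings)
    pano = cubemap_to_equirect(faces, settings.pano_width, settings.sampling)
    if grayscale:
        return to_grayscale(pano)
    return pano


# ---------------------------------------------------------------------------
# I/O: PNG panoramas and CSV location manifests
# ---------------------------------------------------------------------------


def save_png(path, raster: np.ndarray) -> None:
    arr = np.asarray(raster)
    if arr.dtype != np.uint8:
        arr = np.clip(np.rint(arr), 0, 255).astype(np.uint8)
    Image.fromarray(arr).save(str(path))


def load_png(path) -> np.ndarray:
    return np.asarray(Image.open(str(path)))


def write_manifest(path, rows: list[tuple[float, float, float, str]]) -> None:
    """CSV manifest of panorama files: columns x_m, y_m, z_m, file."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["x_m", "y_m", "z_m", "file"])
        w.writerows(rows)


def read_manifest(path) -> list[tuple[float, float, float, str]]:
    out = []
    with open(path, newline="") as fh:
        r = csv.reader(fh)
        header = next(r)
        if header[:4] != ["x_m", "y_m", "z_m", "file"]:
            raise ValueError("manifest must have columns x_m, y_m, z_m, file")
        for row in r:
            out.append((float(row[0]), float(row[1]), float(row[2]), row[3]))
    return out


def load_manifest_panoramas(manifest_path) -> tuple[np.ndarray, np.ndarray]:
    """Load user-supplied greyscale panoramas listed in a manifest.

    Returns (positions (N, 3), panoramas (N, H, W) uint8).  Paths in the
    manifest are resolved relative to the manifest file.
    """
    base = Path(manifest_path).parent
    rows = read_manifest(manifest_path)
    positions, panos = [], []
    for x, y, z, fname in rows:
        img = load_png(base / fname)
        panos.append(to_grayscale(img))
        positions.append((x, y, z))
    return np.asarray(positions), np.asarray(panos)
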