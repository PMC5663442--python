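"""Procedural outdoor scenes and a vectorised ray tracer.

The worlds stand in for photogrammetric reconstructions of real nesting
habitats: a textured ground plane with hard cast shadows, scattered trees
(cylindrical trunks topped by ellipsoidal canopies), optional small ground
clutter, a uniform sky, and optionally a distant panorama projected onto a
large sphere.  Shading is ambient-only — every surface returns its albedo,
darkened by a constant factor where the line to the sun is occluded — which
gives hard shadows without any directional shading model.

A scene is fully determined by its :class:`SceneSpec` (including the seed):
two scenes built from equal specs produce bit-identical renders.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import yaml

from .noise import periodic_noise_1d, value_noise_2d

_EPS = 1e-9  # ray-primitive intersection tolerance, metres
_SHADOW_OFFSET = 1e-6  # lift shadow-ray origins off the surface


class SceneSpecError(ValueError):
    """Raised when a scene specification fails validation; names the field."""


# ---------------------------------------------------------------------------
# specification dataclasses
# ---------------------------------------------------------------------------


@dataclass
class GroundTexture:
    """Multi-octave albedo noise on the ground plane.

    ``noise_scale`` is the wavelength of the coarsest octave (metres); each
    octave halves the wavelength, so natural ground carries contrast from
    metre-scale patches down to decimetre detail.
    """

    noise_scale: float = 8.0  # coarsest correlation length, m
    albedo_lo: float = 0.2
    albedo_hi: float = 0.8
    octaves: int = 6
    persistence: float = 0.55


@dataclass
class Tree:
    position: tuple[float, float] = (0.0, 0.0)  # trunk axis (x east, y north), m
    trunk_radius: float = 0.15
    trunk_height: float = 2.0
    canopy_radius: float = 1.0
    albedo: float = 0.25


@dataclass
class Clutter:
    position: tuple[float, float] = (0.0, 0.0)
    radius: float = 0.2  # sphere resting on the ground
    albedo: float = 0.35


@dataclass
class Sun:
    azimuth_deg: float = 135.0  # compass: 0 = north, clockwise through east
    elevation_deg: float = 45.0
    shadow_darkening: float = 0.45  # albedo multiplier inside shadow; 1 = off

    @property
    def direction(self) -> np.ndarray:
        az = math.radians(self.azimuth_deg)
        el = math.radians(self.elevation_deg)
        return np.array(
            [math.sin(az) * math.cos(el), math.cos(az) * math.cos(el), math.sin(el)]
        )


@dataclass
class Background:
    """What a ray that misses every primitive sees.

    ``none``      — the uniform sky colour everywhere.
    ``uniform``   — a single flat colour (the "uniform blue" ablation).
    ``panorama``  — a distant-skyline texture on a sphere of
                    ``sphere_radius_m`` (dark tree-line silhouette below a
                    noisy skyline elevation, sky colour above).
    """

    mode: str = "none"  # none | uniform | panorama
    color: tuple[float, float, float] = (120.0, 160.0, 235.0)
    sphere_radius_m: float = 500.0
    skyline_mean_deg: float = 3.0
    skyline_amp_deg: float = 2.5
    silhouette_albedo: float = 0.22


@dataclass
class SceneSpec:
    seed: int = 0
    ground_extent: float = 50.0  # half-width of the textured region, m
    ground_texture: GroundTexture = field(default_factory=GroundTexture)
    trees: list[Tree] = field(default_factory=list)
    clutter: list[Clutter] = field(default_factory=list)
    sun: Sun = field(default_factory=Sun)
    sky_color: tuple[float, float, float] = (135.0, 190.0, 240.0)
    background: Background = field(default_factory=Background)

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        if self.ground_extent <= 0:
            raise SceneSpecError("ground_extent must be > 0")
        gt = self.ground_texture
        if gt.noise_scale <= 0:
            raise SceneSpecError("ground_texture.noise_scale must be > 0")
        if gt.octaves < 1:
            raise SceneSpecError("ground_texture.octaves must be >= 1")
        for name in ("albedo_lo", "albedo_hi"):
            v = getattr(gt, name)
            if not 0.0 <= v <= 1.0:
                raise SceneSpecError(f"ground_texture.{name} must be in [0, 1]")
        if gt.albedo_lo > gt.albedo_hi:
            raise SceneSpecError("ground_texture.albedo_lo must be <= albedo_hi")
        for i, t in enumerate(self.trees):
            for name in ("trunk_radius", "trunk_height", "canopy_radius"):
                if getattr(t, name) <= 0:
                    raise SceneSpecError(f"trees[{i}].{name} must be > 0")
            if not 0.0 <= t.albedo <= 1.0:
                raise SceneSpecError(f"trees[{i}].albedo must be in [0, 1]")
        for i, c in enumerate(self.clutter):
            if c.radius <= 0:
                raise SceneSpecError(f"clutter[{i}].radius must be > 0")
            if not 0.0 <= c.albedo <= 1.0:
                raise SceneSpecError(f"clutter[{i}].albedo must be in [0, 1]")
        if not 0.0 <= self.sun.elevation_deg <= 90.0:
            raise SceneSpecError("sun.elevation_deg must be in [0, 90]")
        if not 0.0 <= self.sun.shadow_darkening <= 1.0:
            raise SceneSpecError("sun.shadow_darkening must be in [0, 1]")
        if self.background.mode not in ("none", "uniform", "panorama"):
            raise SceneSpecError("background.mode must be none|uniform|panorama")
        if self.background.mode == "panorama" and (
            self.background.sphere_radius_m <= self.ground_extent
        ):
            raise SceneSpecError(
                "background.sphere_radius_m must exceed ground_extent"
            )

    # -- (de)serialisation --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "ground_extent": self.ground_extent,
            "ground_texture": vars(self.ground_texture).copy(),
            "trees": [
                {**vars(t), "position": list(t.position)} for t in self.trees
            ],
            "clutter": [
                {**vars(c), "position": list(c.position)} for c in self.clutter
            ],
            "sun": vars(self.sun).copy(),
            "sky_color": list(self.sky_color),
            "background": {
                **vars(self.background),
                "color": list(self.background.color),
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SceneSpec":
        d = dict(d)
        spec = cls(
            seed=int(d.get("seed", 0)),
            ground_extent=float(d.get("ground_extent", 50.0)),
            ground_texture=GroundTexture(**d.get("ground_texture", {})),
            trees=[
                Tree(**{**t, "position": tuple(t["position"])})
                for t in d.get("trees", [])
            ],
            clutter=[
                Clutter(**{**c, "position": tuple(c["position"])})
                for c in d.get("clutter", [])
            ],
            sun=Sun(**d.get("sun", {})),
            sky_color=tuple(d.get("sky_color", (135.0, 190.0, 240.0))),
            background=Background(
                **{
                    **d.get("background", {}),
                    "color": tuple(d.get("background", {}).get("color", (120.0, 160.0, 235.0))),
                }
            ),
        )
        return spec

    @classmethod
    def from_yaml(cls, path) -> "SceneSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# the scene itself
# ---------------------------------------------------------------------------


class Scene:
    """Renderable scene: primitive arrays plus shading/background evaluators.

    Build with :func:`make_scene`.  ``trace`` is a pure function of
    (scene, origins, directions).
    """

    def __init__(self, spec: SceneSpec):
        spec.validate()
        self.spec = spec
        # solid primitives in declaration order (nearest-hit ties break on it):
        # trunks (cylinders), canopies (spheres), clutter (spheres)
        cyl, sph = [], []
        for t in spec.trees:
            cyl.append((t.position[0], t.position[1], t.trunk_radius, t.trunk_height, t.albedo))
        for t in spec.trees:
            sph.append(
                (t.position[0], t.position[1], t.trunk_height + 0.6 * t.canopy_radius, t.canopy_radius, t.albedo)
            )
        for c in spec.clutter:
            sph.append((c.position[0], c.position[1], c.radius, c.radius, c.albedo))
        self._cyl = np.array(cyl, dtype=np.float64).reshape(-1, 5)
        self._sph = np.array(sph, dtype=np.float64).reshape(-1, 5)
        self._sun_dir = spec.sun.direction

    # -- per-primitive intersection helpers (vectorised over rays) ----------

    def _t_plane(self, o: np.ndarray, d: np.ndarray) -> np.ndarray:
        dz = d[:, 2]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(np.abs(dz) > 0, -o[:, 2] / dz, np.inf)
        return np.where(t > _EPS, t, np.inf)

    def _t_sphere(self, o: np.ndarray, d: np.ndarray, cx, cy, cz, r) -> np.ndarray:
        oc = o - np.array([cx, cy, cz])
        b = np.einsum("ij,ij->i", oc, d)
        c0 = np.einsum("ij,ij->i", oc, oc) - r * r
        disc = b * b - c0
        hit = disc >= 0
        sq = np.sqrt(np.where(hit, disc, 0.0))
        t1 = -b - sq
        t2 = -b + sq
        t = np.where(t1 > _EPS, t1, np.where(t2 > _EPS, t2, np.inf))
        return np.where(hit, t, np.inf)

    def _t_cylinder(self, o: np.ndarray, d: np.ndarray, x0, y0, r, h) -> np.ndarray:
        ox, oy = o[:, 0] - x0, o[:, 1] - y0
        dx, dy = d[:, 0], d[:, 1]
        a = dx * dx + dy * dy
        b = ox * dx + oy * dy
        c0 = ox * ox + oy * oy - r * r
        disc = b * b - a * c0
        ok = (disc >= 0) & (a > 0)
        sq = np.sqrt(np.where(ok, disc, 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = np.where(ok, (-b - sq) / a, np.inf)
            t2 = np.where(ok, (-b + sq) / a, np.inf)
        z1 = o[:, 2] + t1 * d[:, 2]
        z2 = o[:, 2] + t2 * d[:, 2]
        t1 = np.where((t1 > _EPS) & (z1 >= 0) & (z1 <= h), t1, np.inf)
        t2 = np.where((t2 > _EPS) & (z2 >= 0) & (z2 <= h), t2, np.inf)
        t_lat = np.minimum(t1, t2)
        # top cap disk (the bottom sits on the ground)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_cap = np.where(np.abs(d[:, 2]) > 0, (h - o[:, 2]) / d[:, 2], np.inf)
        with np.errstate(invalid="ignore"):
            px = o[:, 0] + t_cap * d[:, 0] - x0
            py = o[:, 1] + t_cap * d[:, 1] - y0
        t_cap = np.where(
            (t_cap > _EPS) & (px * px + py * py <= r * r), t_cap, np.inf
        )
        return np.minimum(t_lat, t_cap)

    def _solid_ts(self, o: np.ndarray, d: np.ndarray) -> list[np.ndarray]:
        ts = []
        for x0, y0, r, h, _ in self._cyl:
            ts.append(self._t_cylinder(o, d, x0, y0, r, h))
        for cx, cy, cz, r, _ in self._sph:
            ts.append(self._t_sphere(o, d, cx, cy, cz, r))
        return ts

    # -- shading ------------------------------------------------------------

    def ground_albedo(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        gt = self.spec.ground_texture
        inside = (np.abs(x) <= self.spec.ground_extent) & (
            np.abs(y) <= self.spec.ground_extent
        )
        v = value_noise_2d(
            x, y, gt.noise_scale, self.spec.seed, octaves=gt.octaves,
            persistence=gt.persistence,
        )
        a = gt.albedo_lo + v * (gt.albedo_hi - gt.albedo_lo)
        return np.where(inside, a, 0.5 * (gt.albedo_lo + gt.albedo_hi))

    def _occluded(self, p: np.ndarray) -> np.ndarray:
        """True where the line from p to the sun hits a trunk/canopy/clutter."""
        n = p.shape[0]
        if n == 0 or (len(self._cyl) == 0 and len(self._sph) == 0):
            return np.zeros(n, dtype=bool)
        d = np.broadcast_to(self._sun_dir, (n, 3))
        occ = np.zeros(n, dtype=bool)
        for t in self._solid_ts(p, d):
            occ |= np.isfinite(t)
        return occ

    def _background(self, o: np.ndarray, d: np.ndarray) -> np.ndarray:
        bg = self.spec.background
        n = o.shape[0]
        if bg.mode == "none":
            return np.broadcast_to(np.asarray(self.spec.sky_color, float), (n, 3)).copy()
        if bg.mode == "uniform":
            return np.broadcast_to(np.asarray(bg.color, float), (n, 3)).copy()
        # panorama sphere centred on the world origin; take the exit point
        r = bg.sphere_radius_m
        b = np.einsum("ij,ij->i", o, d)
        c0 = np.einsum("ij,ij->i", o, o) - r * r
        t = -b + np.sqrt(np.maximum(b * b - c0, 0.0))
        p = o + t[:, None] * d
        az = np.arctan2(p[:, 0], p[:, 1])  # compass, radians
        el = np.degrees(np.arcsin(np.clip(p[:, 2] / np.linalg.norm(p, axis=1), -1, 1)))
        phase = (az / (2 * np.pi)) % 1.0
        skyline = bg.skyline_mean_deg + bg.skyline_amp_deg * (
            2.0 * periodic_noise_1d(phase, 36, self.spec.seed + 7) - 1.0
        )
        shade = 255.0 * bg.silhouette_albedo * (
            0.8 + 0.4 * periodic_noise_1d(phase, 72, self.spec.seed + 13)
        )
        below = el < skyline
        out = np.broadcast_to(np.asarray(self.spec.sky_color, float), (n, 3)).copy()
        out[below] = np.clip(shade[below], 0, 255)[:, None]
        return out

    # -- the tracer ---------------------------------------------------------

    def trace(self, origins: np.ndarray, directions: np.ndarray) -> np.ndarray:
        """Colour (N, 3) in [0, 255] of the nearest hit for each ray.

        ``origins``/``directions`` are (N, 3); directions must be unit length.
        A ray that starts inside a solid primitive hits its exit surface and
        returns that primitive's colour.
        """
        o = np.atleast_2d(np.asarray(origins, dtype=np.float64))
        d = np.atleast_2d(np.asarray(directions, dtype=np.float64))
        if o.shape[0] == 1 and d.shape[0] > 1:
            o = np.broadcast_to(o, d.shape).copy()
        norms = np.linalg.norm(d, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("directions must be unit vectors")
        n = d.shape[0]

        # declaration order: ground plane, trunks, canopies, clutter
        ts = [self._t_plane(o, d)] + self._solid_ts(o, d)
        T = np.stack(ts, axis=0)  # (P, N)
        best = np.argmin(T, axis=0)  # first index wins ties
        tbest = T[best, np.arange(n)]
        miss = ~np.isfinite(tbest)

        colors = np.empty((n, 3), dtype=np.float64)
        p = o + np.where(np.isfinite(tbest), tbest, 0.0)[:, None] * d

        albedo = np.zeros(n)
        normal = np.zeros((n, 3))
        # ground
        sel = (best == 0) & ~miss
        if sel.any():
            albedo[sel] = self.ground_albedo(p[sel, 0], p[sel, 1])
            normal[sel] = (0.0, 0.0, 1.0)
        ncyl = len(self._cyl)
        for i, (x0, y0, r, h, alb) in enumerate(self._cyl):
            sel = (best == 1 + i) & ~miss
            if not sel.any():
                continue
            albedo[sel] = alb
            on_cap = np.abs(p[sel, 2] - h) < 1e-7
            rad = np.stack(
                [p[sel, 0] - x0, p[sel, 1] - y0, np.zeros(sel.sum())], axis=1
            )
            rad /= np.maximum(np.linalg.norm(rad, axis=1, keepdims=True), 1e-300)
            rad[on_cap] = (0.0, 0.0, 1.0)
            normal[sel] = rad
        for i, (cx, cy, cz, r, alb) in enumerate(self._sph):
            sel = (best == 1 + ncyl + i) & ~miss
            if not sel.any():
                continue
            albedo[sel] = alb
            nv = (p[sel] - np.array([cx, cy, cz])) / r
            normal[sel] = nv

        hit = ~miss
        shade = albedo * 255.0
        if self.spec.sun.shadow_darkening < 1.0 and hit.any():
            occ = self._occluded(p[hit] + _SHADOW_OFFSET * normal[hit])
            factor = np.where(occ, self.spec.sun.shadow_darkening, 1.0)
            shade[hit] = shade[hit] * factor
        colors[:] = shade[:, None]
        if miss.any():
            colors[miss] = self._background(o[miss], d[miss])
        return np.clip(colors, 0.0, 255.0)


def make_scene(spec: SceneSpec) -> Scene:
    """Validate a spec and build the deterministic scene it describes."""
    return Scene(spec)


def ray_trace(scene: Scene, origin: Sequence[float], direction: Sequence[float]) -> np.ndarray:
    """Colour (3,) seen along a single ray."""
    return scene.trace(
        np.asarray(origin, float)[None, :], np.asarray(direction, float)[None, :]
    )[0]


# ---------------------------------------------------------------------------
# shipped presets
# ---------------------------------------------------------------------------

PRESET_NAMES = ("site1_like", "site3_like", "four_landmarks")


def load_preset(name: str) -> SceneSpec:
    """Load one of the shipped scene presets by name.

    ``site1_like``     — near trees, ground clutter, strong shadows (a
                         cluttered nesting site).
    ``site3_like``     — a few large scattered trees, open ground (an open
                         woodland park).
    ``four_landmarks`` — four identical equidistant trees at 90° compass
                         spacing around the origin; rotationally aliased.
    """
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    ref = resources.files("catchvol") / "presets" / f"{name}.yaml"
    with resources.as_file(ref) as path:
        return SceneSpec.from_yaml(path)
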