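"""End-to-end experiment runs: grid rendering, references at several
heights, transIDF volumes, catchments, and the two ablations.

A run is described by an :class:`ExperimentConfig` (usually a YAML file):
the scene (a preset name or a full scene spec), the sampling cube, the
reference heights, and the conditions to analyse — horizon masking
(``all`` vs ``above``) and the distant-background treatment (``none``,
``uniform`` or ``panorama``).  Horizon masking is a pixel-domain operation
and reuses the rendered grid stack; changing the background changes what
missed rays see, so each background condition renders its own stack.  The
grid stack is cached in HDF5, so transIDFs for every reference height reuse
one set of renders.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .catchment import CatchmentVolume, catchment_volume
from .idf import GridSpec, IDFVolume, gradient_threshold, trans_idf_from_stack, render_grid_stack
from .panorama import RenderSettings, horizon_mask
from .scene import PRESET_NAMES, SceneSpec, load_preset, make_scene

log = logging.getLogger("catchvol")


class ConfigError(ValueError):
    """Fatal configuration problem; message names the offending field."""


@dataclass
class ExperimentConfig:
    scene: str | dict = "site3_like"  # preset name or SceneSpec dict
    side_m: float = 2.0
    spacing_m: float = 0.2
    center: tuple[float, float, float] = (0.0, 0.0, 1.2)
    reference_heights_m: list[float] = field(default_factory=lambda: [0.2, 2.0])
    mask_modes: list[str] = field(default_factory=lambda: ["all"])
    backgrounds: list[str] = field(default_factory=lambda: ["none"])
    threshold_fraction: float = 0.10
    seed: int = 0
    face_res: int = 32
    pano_width: int = 192
    output_dir: str = "runs/experiment"

    # -- validation and construction ---------------------------------------

    def validate(self) -> None:
        n = self.side_m / self.spacing_m
        if abs(n - round(n)) > 1e-6:
            raise ConfigError(
                f"side_m/spacing_m = {n} is not an integer; grid counts must "
                "satisfy the inclusive round(side/spacing)+1 rule"
            )
        for m in self.mask_modes:
            if m not in ("all", "above"):
                raise ConfigError(f"mask_modes entry {m!r} must be 'all' or 'above'")
        for b in self.backgrounds:
            if b not in ("none", "uniform", "panorama"):
                raise ConfigError(
                    f"backgrounds entry {b!r} must be none|uniform|panorama"
                )
        if isinstance(self.scene, str) and self.scene not in PRESET_NAMES:
            raise ConfigError(f"scene preset {self.scene!r} unknown")
        if not 0 < self.threshold_fraction <= 1:
            raise ConfigError("threshold_fraction must be in (0, 1]")
        zmin = self.center[2] - self.side_m / 2
        zmax = self.center[2] + self.side_m / 2
        for hgt in self.reference_heights_m:
            if not zmin <= hgt <= zmax:
                raise ConfigError(
                    f"reference_heights_m entry {hgt} outside grid z-range "
                    f"[{zmin}, {zmax}]"
                )

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["center"] = tuple(d.get("center", (0.0, 0.0, 1.2)))
        return cls(**d)

    def to_dict(self) -> dict:
        d = vars(self).copy()
        d["center"] = list(self.center)
        return d

    # -- derived pieces ------------------------------------------------------

    def grid(self) -> GridSpec:
        return GridSpec.from_side(self.side_m, self.spacing_m, self.center)

    def scene_spec(self, background: str) -> SceneSpec:
        if isinstance(self.scene, str):
            spec = load_preset(self.scene)
        else:
            spec = SceneSpec.from_dict(self.scene)
        spec.seed = spec.seed + self.seed  # per-run reseed, still deterministic
        spec.background.mode = background
        return spec

    def settings(self) -> RenderSettings:
        return RenderSettings(face_res=self.face_res, pano_width=self.pano_width)


@dataclass
class ExperimentBundle:
    """Paths and summaries of one finished run."""

    root: Path
    manifest: dict
    conditions: dict[str, dict]  # condition name -> summary dict

    @property
    def condition_dirs(self) -> dict[str, Path]:
        return {name: self.root / name for name in self.conditions}


def _config_hash(cfg: ExperimentConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _reference_index(grid: GridSpec, height_m: float) -> tuple[int, int, int]:
    """Grid index at the horizontal centre, at the grid plane nearest the
    requested height above ground."""
    i = (grid.counts[0] - 1) // 2
    j = (grid.counts[1] - 1) // 2
    k = int(np.argmin(np.abs(grid.axis_coords(2) - height_m)))
    return (i, j, k)


def run_experiment(config: ExperimentConfig, output_dir=None) -> ExperimentBundle:
    """Execute a full experiment and write its result bundle to disk.

    Per background condition the grid stack is rendered once (HDF5-cached,
    so reruns resume from it); every reference height × mask mode reuses it.
    Each condition directory receives the IDF volume (HDF5), axis transects
    through the reference (CSV), and the catchment volume (PLY + CSV + JSON
    summary including the threshold used).
    """
    config.validate()
    root = Path(output_dir if output_dir is not None else config.output_dir)
    root.mkdir(parents=True, exist_ok=True)
    grid = config.grid()
    settings = config.settings()
    conditions: dict[str, dict] = {}

    for bg in config.backgrounds:
        spec = config.scene_spec(bg)
        scene = make_scene(spec)
        stack_path = root / f"stack_{bg}.h5"
        log.info("rendering %d panoramas for background=%s", grid.n_points, bg)
        stack = render_grid_stack(scene, grid, settings, cache_path=stack_path)
        for height in config.reference_heights_m:
            ref_idx = _reference_index(grid, height)
            for mask_mode in config.mask_modes:
                name = f"ref{height:g}m_{mask_mode}_{bg}"
                cdir = root / name
                cdir.mkdir(exist_ok=True)
                vol = trans_idf_from_stack(stack, grid, ref_idx, mask_mode)
                vol.save(cdir / "idf.h5")
                for axis, fixed in (
                    ("x", {"j": ref_idx[1], "k": ref_idx[2]}),
                    ("y", {"i": ref_idx[0], "k": ref_idx[2]}),
                    ("z", {"i": ref_idx[0], "j": ref_idx[1]}),
                ):
                    vol.transect_to_csv(cdir / f"transect_{axis}.csv", axis, **fixed)
                ref_pano = stack[ref_idx]
                mask = horizon_mask(mask_mode, ref_pano.shape)
                thr = gradient_threshold(ref_pano, mask, config.threshold_fraction)
                cv = catchment_volume(vol, thr)
                cv.to_ply(cdir / "catchment.ply")
                cv.to_csv(cdir / "catchment.csv")
                cv.summary_to_json(cdir / "catchment.json")
                summary = cv.summary()
                summary.update(
                    {
                        "reference_height_m": height,
                        "mask_mode": mask_mode,
                        "background": bg,
                    }
                )
                conditions[name] = summary
                log.info(
                    "condition %s: threshold %.4g/m, %d/%d successes",
                    name,
                    thr,
                    cv.success_count,
                    grid.n_points,
                )

    manifest = {
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "grid_counts": list(grid.counts),
        "rendered_panoramas": grid.n_points * len(config.backgrounds),
        "versions": {"catchvol": __version__, "numpy": np.__version__},
        "conditions": conditions,
    }
    with open(root / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return ExperimentBundle(root=root, manifest=manifest, conditions=conditions)


# ---------------------------------------------------------------------------
# condition comparison
# ---------------------------------------------------------------------------


def _load_condition(cdir) -> tuple[IDFVolume, dict, np.ndarray]:
    cdir = Path(cdir)
    vol = IDFVolume.load(cdir / "idf.h5")
    with open(cdir / "catchment.json") as fh:
        summary = json.load(fh)
    success = np.zeros(vol.grid.counts, dtype=bool)
    with open(cdir / "catchment.csv") as fh:
        next(fh)
        for line in fh:
            i, j, k, _, _, _, status = line.strip().split(",")
            success[int(i), int(j), int(k)] = status == "success"
    return vol, summary, success


def compare_conditions(cond_a, cond_b, out_path=None) -> dict:
    """Compare two condition directories sharing a grid and reference.

    Reports per-condition success counts, the signed difference, and the
    voxel sets unique to each; optionally written as JSON.
    """
    vol_a, sum_a, succ_a = _load_condition(cond_a)
    vol_b, sum_b, succ_b = _load_condition(cond_b)
    if vol_a.grid != vol_b.grid:
        raise ValueError("conditions must share a grid")
    if tuple(vol_a.reference_index) != tuple(vol_b.reference_index):
        raise ValueError("conditions must share a reference index")
    only_a = succ_a & ~succ_b
    only_b = succ_b & ~succ_a
    report = {
        "condition_a": str(cond_a),
        "condition_b": str(cond_b),
        "success_a": int(succ_a.sum()),
        "success_b": int(succ_b.sum()),
        "success_difference_a_minus_b": int(succ_a.sum()) - int(succ_b.sum()),
        "voxels_only_in_a": int(only_a.sum()),
        "voxels_only_in_b": int(only_b.sum()),
        "voxels_in_both": int((succ_a & succ_b).sum()),
        "threshold_a": sum_a["threshold_grey_per_m"],
        "threshold_b": sum_b["threshold_grey_per_m"],
    }
    if out_path is not None:
        with open(out_path, "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return report
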