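import numpy as np
import pytest

import catchvol as cv
from catchvol.idf import GridSpec, IDFVolume
from catchvol.scene import GroundTexture, SceneSpec, Sun, Tree, make_scene

# small render settings keep the suite fast; conventions are identical to the
# 128-face / 384-wide reference configuration
SMALL = cv.RenderSettings(face_res=16, pano_width=96)
MEDIUM = cv.RenderSettings(face_res=32, pano_width=192)


@pytest.fixture(scope="session")
def small_settings():
    return SMALL


@pytest.fixture(scope="session")
def flat_scene():
    """Treeless scene with constant ground albedo (fully uniform views)."""
    spec = SceneSpec(
        seed=1,
        ground_texture=GroundTexture(noise_scale=0.5, albedo_lo=0.6, albedo_hi=0.6),
        sun=Sun(shadow_darkening=1.0),
    )
    return make_scene(spec)


@pytest.fixture(scope="session")
def textured_scene():
    """One tree plus textured ground: finite-distance contrast everywhere."""
    spec = SceneSpec(
        seed=7,
        ground_texture=GroundTexture(noise_scale=0.3, albedo_lo=0.2, albedo_hi=0.8),
        trees=[Tree(position=(3.0, 2.0), trunk_height=2.5, canopy_radius=1.5)],
        sun=Sun(azimuth_deg=120.0, elevation_deg=40.0, shadow_darkening=0.4),
    )
    return make_scene(spec)


@pytest.fixture(scope="session")
def site3_scene():
    return make_scene(cv.load_preset("site3_like"))


@pytest.fixture(scope="session")
def site3_stack_11(site3_scene, tmp_path_factory):
    """site3_like panoramas on the 11^3 grid at 0.2 m spacing (shared)."""
    grid = GridSpec.from_side(2.0, 0.2, (0.0, 0.0, 1.2))
    path = tmp_path_factory.mktemp("stacks") / "site3_11.h5"
    stack = cv.render_grid_stack(site3_scene, grid, MEDIUM, cache_path=path)
    return stack, grid


def bowl_volume(counts=(5, 5, 5), spacing=0.2, ref=None) -> IDFVolume:
    """Synthetic convex transIDF: value = distance to the reference."""
    grid = GridSpec((0.0, 0.0, 1.0), spacing, counts)
    if ref is None:
        ref = tuple((c - 1) // 2 for c in counts)
    idx = np.stack(np.meshgrid(*(np.arange(c) for c in counts), indexing="ij"), axis=-1)
    vals = spacing * np.linalg.norm(idx - np.asarray(ref), axis=-1)
    return IDFVolume(grid, ref, vals)


@pytest.fixture
def bowl():
    return bowl_volume()
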