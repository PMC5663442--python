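"""Seeded, hash-based value noise.

Band-limited lattice value noise used for the ground texture and for the
distant-panorama skyline.  Everything here is a pure function of the integer
lattice coordinates and the seed, so two scenes built from the same spec are
bit-identical regardless of call order or array chunking.
"""

from __future__ import annotations

import numpy as np

_M1 = np.uint64(0x9E3779B97F4A7C15)
_M2 = np.uint64(0xC2B2AE3D27D4EB4F)
_M3 = np.uint64(0x165667B19E3779F9)
_MIX = np.uint64(0xFF51AFD7ED558CCD)


def _hash01(ix: np.ndarray, iy: np.ndarray, seed: int) -> np.ndarray:
    """Uniform [0, 1) value attached to each integer lattice point."""
    with np.errstate(over="ignore"):
        h = (
            ix.astype(np.int64).astype(np.uint64) * _M1
            ^ iy.astype(np.int64).astype(np.uint64) * _M2
            ^ np.uint64(seed & 0xFFFFFFFFFFFFFFFF) * _M3
        )
        h ^= h >> np.uint64(33)
        h *= _MIX
        h ^= h >> np.uint64(33)
    return (h >> np.uint64(11)).astype(np.float64) / float(1 << 53)


def _smoothstep(t: np.ndarray) -> np.ndarray:
    return t * t * (3.0 - 2.0 * t)


def value_noise_2d(
    x: np.ndarray,
    y: np.ndarray,
    scale: float,
    seed: int,
    octaves: int = 3,
    persistence: float = 0.5,
) -> np.ndarray:
    """Multi-octave value noise in [0, 1].

    ``scale`` is the correlation length in metres of the lowest octave; each
    further octave halves the wavelength and multiplies the amplitude by
    ``persistence``.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    out = np.zeros(np.broadcast(x, y).shape, dtype=np.float64)
    amp, norm, freq = 1.0, 0.0, 1.0 / max(scale, 1e-12)
    for octave in range(octaves):
        fx, fy = x * freq, y * freq
        ix, iy = np.floor(fx).astype(np.int64), np.floor(fy).astype(np.int64)
        tx, ty = _smoothstep(fx - ix), _smoothstep(fy - iy)
        s = seed * 1009 + octave  # decorrelate octaves
        v00 = _hash01(ix, iy, s)
        v10 = _hash01(ix + 1, iy, s)
        v01 = _hash01(ix, iy + 1, s)
        v11 = _hash01(ix + 1, iy + 1, s)
        v = (v00 * (1 - tx) + v10 * tx) * (1 - ty) + (v01 * (1 - tx) + v11 * tx) * ty
        out += amp * v
        norm += amp
        amp *= persistence
        freq *= 2.0
    return out / norm


def periodic_noise_1d(phase: np.ndarray, cells: int, seed: int) -> np.ndarray:
    """Value noise in [0, 1] periodic in ``phase`` over [0, 1).

    Used for the skyline height of the distant background panorama: the
    texture must wrap seamlessly in azimuth.
    """
    f = np.asarray(phase, dtype=np.float64) * cells
    i0 = np.floor(f).astype(np.int64)
    t = _smoothstep(f - i0)
    i0 = np.mod(i0, cells)
    i1 = np.mod(i0 + 1, cells)
    zero = np.zeros_like(i0)
    return _hash01(i0, zero, seed) * (1 - t) + _hash01(i1, zero, seed) * t
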