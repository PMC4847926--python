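"""Panoramic scene primitives: preprocessing, rotation, and SAD comparison.

A :class:`Scene` is the unit of every comparison in this package: a square
matrix of quantized gray levels with everything outside the inscribed circle
set to level 0 (a "circularized" fisheye snapshot).  The sole similarity
measure is the summed absolute pixel-by-pixel difference (SAD).

Conventions shared by every module:

* Compass angles are degrees in [0, 360) with 0° along the +row axis and
  90° along the +column axis.
* A positive rotation angle turns image content clockwise in that frame
  (the agent turning clockwise), i.e. content at image azimuth ``a`` moves
  to azimuth ``a - angle``.
* Rotation resamples by nearest neighbor; quarter turns are exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np

__all__ = [
    "Scene",
    "circular_mask",
    "preprocess",
    "equalize",
    "quantize",
    "rotate_scene",
    "sad",
    "ridf_curve",
    "best_rotation_match",
]

# Equalization maps through the exact empirical CDF (one bin per distinct
# input value), normalized so the smallest value maps to 0 and the largest
# to 1.  Recorded in manifests; any bin count >= G would do.
EQUALIZATION = "empirical-cdf-minmax"
MASK_CONVENTION = "inscribed-circle; pixels strictly outside level 0"
ROTATION_CONVENTION = "positive = clockwise (compass 0=+row, 90=+col)"


@dataclass
class Scene:
    """A square, circularly masked, gray-quantized panoramic snapshot.

    Parameters
    ----------
    matrix
        ``(N, N)`` integer array of gray levels in ``[0, gray_levels - 1]``.
    gray_levels
        Number of quantization levels ``G`` (>= 2).
    meta
        Optional provenance (grid row/col, heading, source id, ...).
    """

    matrix: np.ndarray
    gray_levels: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("scene matrix must be square")
        if self.gray_levels < 2:
            raise ValueError("gray_levels must be >= 2")

    @property
    def resolution(self) -> int:
        return self.matrix.shape[0]

    def copy(self) -> "Scene":
        return Scene(self.matrix.copy(), self.gray_levels, dict(self.meta))


@lru_cache(maxsize=64)
def circular_mask(n: int) -> np.ndarray:
    """Boolean mask of the inscribed circle of diameter ``n`` (True = inside)."""
    c = (n - 1) / 2.0
    r = np.arange(n) - c
    d2 = r[:, None] ** 2 + r[None, :] ** 2
    m = d2 <= (n / 2.0) ** 2
    m.setflags(write=False)
    return m


def _rot_coeffs(angle_deg: float) -> tuple[float, float]:
    """cos/sin of an angle, exact for multiples of 90 degrees."""
    a = angle_deg % 360.0
    quarters = {0.0: (1.0, 0.0), 90.0: (0.0, 1.0), 180.0: (-1.0, 0.0), 270.0: (0.0, -1.0)}
    if a in quarters:
        return quarters[a]
    rad = math.radians(a)
    return math.cos(rad), math.sin(rad)


@lru_cache(maxsize=4096)
def _rotation_map(n: int, angle_key: float) -> np.ndarray:
    """Flat gather indices implementing a clockwise content rotation.

    Output pixel at centered offset ``(dr, dc)`` samples the input at the
    offset rotated by ``+angle`` (content at azimuth a ends up at a-angle).
    """
    cosa, sina = _rot_coeffs(angle_key)
    c = (n - 1) / 2.0
    d = np.arange(n) - c
    dr = d[:, None]
    dc = d[None, :]
    fr = c + dr * cosa - dc * sina
    fc = c + dr * sina + dc * cosa
    sr = np.rint(fr).astype(np.intp)
    sc = np.rint(fc).astype(np.intp)
    np.clip(sr, 0, n - 1, out=sr)
    np.clip(sc, 0, n - 1, out=sc)
    # rounding can push a rim source just outside the circle even though the
    # true rotated coordinate is inside; fall back to the nearest in-circle
    # neighbor so rotationally symmetric scenes stay invariant
    inside = circular_mask(n)
    bad = np.argwhere(inside & ~inside[sr, sc])
    for r, col in bad:
        tr, tc = fr[r, col], fc[r, col]
        cands = [(int(math.floor(tr)) + i, int(math.floor(tc)) + j)
                 for i in (0, 1) for j in (0, 1)]
        cands = [(a, b) for a, b in cands
                 if 0 <= a < n and 0 <= b < n and inside[a, b]]
        if cands:
            sr[r, col], sc[r, col] = min(
                cands, key=lambda p: (p[0] - tr) ** 2 + (p[1] - tc) ** 2)
    idx = (sr * n + sc).ravel()
    idx.setflags(write=False)
    return idx


def rotation_map(n: int, angle_deg: float) -> np.ndarray:
    return _rotation_map(n, round(float(angle_deg) % 360.0, 9))


def equalize(img: np.ndarray) -> np.ndarray:
    """Histogram-equalize to [0, 1] via the exact empirical CDF.

    The CDF is renormalized so the lowest occurring value maps to 0 and the
    highest to 1; a constant image maps to 0.5.
    """
    img = np.asarray(img, dtype=float)
    vals, inv, counts = np.unique(img, return_inverse=True, return_counts=True)
    if vals.size == 1:
        return np.full(img.shape, 0.5)
    cdf = np.cumsum(counts) / img.size
    lo = cdf[0]
    eq = (cdf - lo) / (1.0 - lo)
    return eq[inv].reshape(img.shape)


def quantize(img: np.ndarray, gray_levels: int) -> np.ndarray:
    """Uniform floor-based quantization of [0, 1] into ``gray_levels`` bins.

    The top edge is inclusive (1.0 maps to level G-1).  Idempotent on the
    level grid: ``quantize(levels / (G - 1), G) == levels``.
    """
    if gray_levels < 2:
        raise ValueError("gray_levels must be >= 2")
    lv = np.floor(np.asarray(img, dtype=float) * gray_levels).astype(np.int16)
    return np.clip(lv, 0, gray_levels - 1)


def _area_resample(img: np.ndarray, n: int) -> np.ndarray:
    """Exact area-average resample of a square image to ``n`` x ``n``."""
    side = img.shape[0]
    if side == n:
        return np.asarray(img, dtype=float)
    if side % n == 0:
        f = side // n
        return img.reshape(n, f, n, f).mean(axis=(1, 3))
    # overlap weights: output cell i covers [i*side/n, (i+1)*side/n)
    w = np.zeros((n, side))
    scale = side / n
    for i in range(n):
        lo, hi = i * scale, (i + 1) * scale
        j0, j1 = int(math.floor(lo)), int(math.ceil(hi))
        for j in range(j0, min(j1, side)):
            w[i, j] = min(hi, j + 1) - max(lo, j)
    w /= w.sum(axis=1, keepdims=True)
    return w @ np.asarray(img, dtype=float) @ w.T


def apply_mask(matrix: np.ndarray) -> np.ndarray:
    out = np.asarray(matrix).copy()
    out[~circular_mask(out.shape[0])] = 0
    return out


def preprocess(frame: np.ndarray, resolution: int, gray_levels: int,
               meta: dict | None = None) -> Scene:
    """Run the full capture pipeline on a raw frame.

    Pipeline order: grayscale (channel average) -> centered square crop ->
    histogram equalization -> area-average downsample to N x N -> uniform
    quantization into G levels -> circular mask.

    Parameters
    ----------
    frame
        2-D intensity or 3-channel image, any numeric dtype.
    resolution
        Output side length N (the sensor resolution).
    gray_levels
        Gray depth G; the laboratory configuration is N=100, G=10 and the
        corridor configuration N=100, G=100.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0:
        raise ValueError("empty frame")
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame intensities must be finite")
    if gray_levels < 2:
        raise ValueError("gray_levels must be >= 2")
    if resolution < 1:
        raise ValueError("resolution must be >= 1")
    if frame.ndim == 3:
        frame = frame.mean(axis=2)
    if frame.ndim != 2:
        raise ValueError("frame must be 2-D or 3-channel")
    h, w = frame.shape
    side = min(h, w)
    r0, c0 = (h - side) // 2, (w - side) // 2
    sq = frame[r0:r0 + side, c0:c0 + side]
    eq = equalize(sq)
    small = _area_resample(eq, resolution)
    levels = quantize(np.clip(small, 0.0, 1.0), gray_levels)
    return Scene(apply_mask(levels), gray_levels, meta or {})


def rotate_scene(scene: Scene, angle_deg: float) -> Scene:
    """Rotate scene content clockwise by ``angle_deg`` (nearest neighbor).

    Angles reduce modulo 360; the circular mask is re-applied.  Quarter
    turns are lossless permutations of the in-circle pixels.
    """
    n = scene.resolution
    rotated = scene.matrix.ravel()[rotation_map(n, angle_deg)].reshape(n, n)
    return Scene(apply_mask(rotated), scene.gray_levels, dict(scene.meta))


def _check_compat(a: Scene, b: Scene) -> None:
    if a.matrix.shape != b.matrix.shape:
        raise ValueError("scenes differ in resolution")
    if a.gray_levels != b.gray_levels:
        raise ValueError("scenes differ in gray depth")


def sad(a: Scene, b: Scene) -> int:
    """Summed absolute pixel-by-pixel difference between two scenes."""
    _check_compat(a, b)
    return int(np.abs(a.matrix.astype(np.int64) - b.matrix.astype(np.int64)).sum())


def _angle_grid(angle_step: float) -> np.ndarray:
    if angle_step <= 0:
        raise ValueError("angle_step must be positive")
    k = 360.0 / angle_step
    if abs(k - round(k)) > 1e-9:
        raise ValueError("360 must be divisible by angle_step")
    return np.arange(int(round(k))) * float(angle_step)


def ridf_curve(scene: Scene, angle_step: float = 1.0) -> np.ndarray:
    """Rotational image difference function of a scene against itself.

    Entry k is ``sad(rotate_scene(scene, k * angle_step), scene)``; entry 0
    is always 0.
    """
    angles = _angle_grid(angle_step)
    flat = scene.matrix.ravel().astype(np.int64)
    n = scene.resolution
    mask = ~circular_mask(n).ravel()
    out = np.empty(angles.size, dtype=np.int64)
    for i, a in enumerate(angles):
        rot = flat[rotation_map(n, a)].copy()
        rot[mask] = 0
        out[i] = np.abs(rot - flat).sum()
    return out


def best_rotation_match(candidate: Scene, memory: Sequence[Scene],
                        angle_step: float = 1.0) -> tuple[int, float, int]:
    """Global best match of a candidate view against a memory bank.

    Rotates the candidate through a full turn at ``angle_step`` intervals and
    compares every rotation to every memory scene (order-free), returning
    ``(min_sad, best_angle_deg, best_memory_index)``.  Ties break toward the
    smallest angle, then the smallest memory index.
    """
    memory = list(memory)
    if not memory:
        raise ValueError("memory must be non-empty")
    for m in memory:
        _check_compat(candidate, m)
    angles = _angle_grid(angle_step)
    n = candidate.resolution
    flat = candidate.matrix.ravel().astype(np.int16)
    mask = ~circular_mask(n).ravel()
    mem = np.stack([m.matrix.ravel() for m in memory]).astype(np.int16)
    best = (np.iinfo(np.int64).max, 0.0, -1)
    for a in angles:
        rot = flat[rotation_map(n, a)].copy()
        rot[mask] = 0
        diffs = np.abs(rot[None, :] - mem).sum(axis=1, dtype=np.int64)
        j = int(np.argmin(diffs))
        if diffs[j] < best[0]:
            best = (int(diffs[j]), float(a), j)
    return best
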