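"""Whole-landscape visual information analyses.

Works on a :class:`GridLandscape` — a T x P survey grid of scenes (rows =
transects, columns = points along each transect) at a fixed physical pitch.
Provides the familiarity landscape (mean SAD of each scene against all
scenes), per-scene "volcano" difference fields, averaged translational (IDF)
and rotational (RIDF) difference curves with their half-maximal p50
catchment widths, and path-relative trough and quiver fields.

Normalization follows the maximal-difference-per-resolution rule: IDF values
are divided by the single largest pairwise SAD in the landscape, RIDF values
by the largest rotational SAD, so averaged curves lie in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

from .scene import Scene, circular_mask, rotation_map

if TYPE_CHECKING:  # pragma: no cover
    from .path import TrainingPath

__all__ = [
    "GridLandscape",
    "DifferenceField",
    "IDFSummary",
    "RIDFSummary",
    "QuiverField",
    "pairwise_sad_matrix",
    "familiarity_landscape",
    "volcano",
    "idf_summary",
    "ridf_summary",
    "path_trough",
    "quiver_field",
]


@dataclass
class GridLandscape:
    """T x P grid of scenes with physical spacing (default 12.7 cm)."""

    stack: np.ndarray            # (T, P, N, N) integer gray levels
    gray_levels: int
    spacing_m: float = 0.127
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.stack = np.asarray(self.stack)
        if self.stack.ndim != 4 or self.stack.shape[2] != self.stack.shape[3]:
            raise ValueError("stack must be (T, P, N, N)")
        if self.spacing_m <= 0:
            raise ValueError("spacing must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.stack.shape[:2]

    @property
    def resolution(self) -> int:
        return self.stack.shape[2]

    @property
    def n_scenes(self) -> int:
        t, p = self.shape
        return t * p

    def scene(self, row: int, col: int) -> Scene:
        t, p = self.shape
        if not (0 <= row < t and 0 <= col < p):
            raise IndexError("grid index out of bounds")
        return Scene(self.stack[row, col], self.gray_levels,
                     {"row": row, "col": col})

    @classmethod
    def from_scenes(cls, scenes, gray_levels: int, spacing_m: float = 0.127,
                    meta: dict | None = None) -> "GridLandscape":
        """Build from a nested (T x P) sequence of Scene objects."""
        stack = np.stack([np.stack([s.matrix for s in row]) for row in scenes])
        return cls(stack, gray_levels, spacing_m, meta or {})


@dataclass
class DifferenceField:
    values: np.ndarray           # (T, P) non-negative
    kind: str                    # mean-vs-all | vs-focal | vs-path
    spacing_m: float = 0.127


@dataclass
class IDFSummary:
    distances_m: np.ndarray
    mean_norm_diff: np.ndarray
    counts: np.ndarray
    p50_m: float | None


@dataclass
class RIDFSummary:
    angles_deg: np.ndarray
    mean_norm_diff: np.ndarray
    p50_deg: float | None


@dataclass
class QuiverField:
    best_angle_deg: np.ndarray   # (T, P)
    strength: np.ndarray         # (T, P) in [0, 1]


def _flat_stack(landscape: GridLandscape) -> np.ndarray:
    t, p = landscape.shape
    n = landscape.resolution
    return landscape.stack.reshape(t * p, n * n).astype(np.int16)


def pairwise_sad_matrix(landscape: GridLandscape, chunk: int = 256) -> np.ndarray:
    """Full (T*P) x (T*P) matrix of unrotated pairwise SADs."""
    flat = _flat_stack(landscape)
    m = flat.shape[0]
    out = np.empty((m, m), dtype=np.int64)
    for i0 in range(0, m, chunk):
        i1 = min(i0 + chunk, m)
        d = np.abs(flat[i0:i1, None, :].astype(np.int32) - flat[None, :, :])
        out[i0:i1] = d.sum(axis=2, dtype=np.int64)
    return out


def familiarity_landscape(landscape: GridLandscape) -> DifferenceField:
    """Mean unrotated SAD of each grid scene against all scenes (incl. self)."""
    m = pairwise_sad_matrix(landscape)
    t, p = landscape.shape
    return DifferenceField(m.mean(axis=1).reshape(t, p), "mean-vs-all",
                           landscape.spacing_m)


def volcano(landscape: GridLandscape, focal: tuple[int, int]) -> DifferenceField:
    """Unrotated SAD of the focal scene against every grid scene."""
    t, p = landscape.shape
    r, c = focal
    if not (0 <= r < t and 0 <= c < p):
        raise IndexError("focal index out of bounds")
    flat = _flat_stack(landscape)
    f = flat[r * p + c].astype(np.int32)
    vals = np.abs(flat.astype(np.int32) - f[None, :]).sum(axis=1, dtype=np.int64)
    return DifferenceField(vals.reshape(t, p).astype(float), "vs-focal",
                           landscape.spacing_m)


def _p50(x: np.ndarray, curve: np.ndarray) -> float | None:
    """First upward crossing of half the curve's own maximum, interpolated."""
    top = float(curve.max(initial=0.0))
    if top <= 0:
        return None
    half = top / 2.0
    for i in range(1, curve.size):
        if curve[i] >= half:
            lo, hi = curve[i - 1], curve[i]
            if hi == lo:
                return float(x[i])
            frac = (half - lo) / (hi - lo)
            return float(x[i - 1] + frac * (x[i] - x[i - 1]))
    return None


def idf_summary(landscape: GridLandscape) -> tuple[IDFSummary, int]:
    """Averaged translational image difference function and its p50.

    For each focal cell, the row (E-W) and column (N-S) slices of its
    volcano are folded at the focal minimum into a falling and a rising
    half-slice — four half-slices per focal cell, so a 40 x 45 grid yields
    7200 vectors.  Boundary cells contribute (possibly length-0) half-slices
    that still count.  The mean at distance d pools every half-slice long
    enough to reach d; values are normalized by the landscape's maximal
    pairwise SAD at this resolution.
    """
    t, p = landscape.shape
    if t * p < 2:
        raise ValueError("landscape needs at least 2 cells")
    m = pairwise_sad_matrix(landscape).reshape(t, p, t, p).astype(float)
    gmax = float(m.max())
    dmax = max(t, p) - 1
    sums = np.zeros(dmax + 1)
    counts = np.zeros(dmax + 1, dtype=np.int64)
    for r in range(t):
        for c in range(p):
            row = m[r, c, r, :]
            col = m[r, c, :, c]
            for half in (row[c:], row[c::-1], col[r:], col[r::-1]):
                k = half.size
                sums[:k] += half
                counts[:k] += 1
    vector_count = 4 * t * p
    mean = np.divide(sums, counts, out=np.zeros_like(sums), where=counts > 0)
    if gmax > 0:
        mean = mean / gmax
    dist = np.arange(dmax + 1) * landscape.spacing_m
    p50 = _p50(dist, mean) if gmax > 0 else None
    return IDFSummary(dist, mean, counts, p50), vector_count


def ridf_summary(landscape: GridLandscape,
                 angle_step: float = 1.0) -> tuple[RIDFSummary, int]:
    """Averaged rotational image difference function and its p50.

    Each scene's full-turn RIDF is folded at 180° into its rising (0 -> 180)
    and falling (360 -> 180, reversed) halves — two vectors per scene, so a
    40 x 45 grid yields 3600.  Values are normalized by the landscape's
    maximal rotational SAD at this resolution.
    """
    if angle_step <= 0:
        raise ValueError("angle_step must be positive")
    k = 360.0 / angle_step
    if abs(k - round(k)) > 1e-9:
        raise ValueError("360 must be divisible by angle_step")
    k = int(round(k))
    t, p = landscape.shape
    n = landscape.resolution
    flat = _flat_stack(landscape)
    mask = ~circular_mask(n).ravel()
    curves = np.empty((t * p, k), dtype=np.int64)
    for i in range(k):
        rot = flat[:, rotation_map(n, i * angle_step)].copy()
        rot[:, mask] = 0
        curves[:, i] = np.abs(rot.astype(np.int32) - flat).sum(axis=1, dtype=np.int64)
    gmax = float(curves.max())
    nhalf = int(np.floor(180.0 / angle_step + 1e-9))
    rising = curves[:, :nhalf + 1].astype(float)
    falling = np.concatenate([curves[:, :1], curves[:, :k - nhalf - 1:-1]],
                             axis=1).astype(float)
    vector_count = 2 * t * p
    mean = (rising.sum(axis=0) + falling.sum(axis=0)) / (2 * t * p)
    if gmax > 0:
        mean = mean / gmax
    angles = np.arange(nhalf + 1) * angle_step
    p50 = _p50(angles, mean) if gmax > 0 else None
    return RIDFSummary(angles, mean, p50), vector_count


def _match_field(landscape: GridLandscape, path: "TrainingPath",
                 angle_step: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell (min SAD, best angle) over all path scenes and rotations.

    Ties break toward the smallest rotation angle, matching
    :func:`scenefam.scene.best_rotation_match`.
    """
    if len(path.scenes) == 0:
        raise ValueError("path must be non-empty")
    if angle_step <= 0:
        raise ValueError("angle_step must be positive")
    kf = 360.0 / angle_step
    if abs(kf - round(kf)) > 1e-9:
        raise ValueError("360 must be divisible by angle_step")
    k = int(round(kf))
    t, p = landscape.shape
    n = landscape.resolution
    flat = _flat_stack(landscape)
    mask = ~circular_mask(n).ravel()
    mem = np.stack([s.matrix.ravel() for s in path.scenes]).astype(np.int16)
    best = np.full(t * p, np.iinfo(np.int64).max, dtype=np.int64)
    best_angle = np.zeros(t * p)
    for i in range(k):
        a = i * angle_step
        rot = flat[:, rotation_map(n, a)].copy()
        rot[:, mask] = 0
        d = np.abs(rot[:, None, :].astype(np.int32) - mem[None, :, :]).sum(
            axis=2, dtype=np.int64).min(axis=1)
        better = d < best
        best[better] = d[better]
        best_angle[better] = a
    return best.reshape(t, p).astype(float), best_angle.reshape(t, p)


def path_trough(landscape: GridLandscape, path: "TrainingPath",
                angle_step: float = 1.0) -> DifferenceField:
    """Rotation-minimized SAD of every grid cell to the nearest path scene."""
    vals, _ = _match_field(landscape, path, angle_step)
    return DifferenceField(vals, "vs-path", landscape.spacing_m)


def quiver_field(landscape: GridLandscape, path: "TrainingPath",
                 angle_step: float = 1.0) -> QuiverField:
    """Best-match rotation (arrow direction) and strength (arrow length).

    Strength is 1 - value / max(value) over the trough field, clipped to
    [0, 1]; an exact unrotated copy of a path scene scores strength 1 at
    angle 0.
    """
    vals, angles = _match_field(landscape, path, angle_step)
    top = float(vals.max())
    strength = np.ones_like(vals) if top <= 0 else np.clip(1.0 - vals / top, 0.0, 1.0)
    return QuiverField(angles % 360.0, strength)
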