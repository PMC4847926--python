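"""Training paths: waypoint rasterization and novel-path ingestion.

A training path is the agent's memory: the ordered grid scenes a training
excursion would intersect, each rotated to its travel bearing so it matches
what a traveler heading along the segment would see.  Bearings follow the
shared compass convention (0° = +row/transect axis, 90° = +column/point
axis, increasing clockwise).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .scene import Scene, preprocess, rotate_scene
from .landscape import GridLandscape

__all__ = ["Waypoint", "TrainingPath", "bearing", "rasterize_path",
           "ingest_novel_path"]


@dataclass(frozen=True)
class Waypoint:
    """Continuous grid coordinates (grid units; fractional allowed)."""
    row: float
    col: float


@dataclass
class TrainingPath:
    """Ordered path scenes, each stored pre-rotated to its segment bearing.

    ``cells`` holds the (row, col) grid cell of each scene, or None for
    externally captured scenes with unknown grid position; ``end_cell`` is
    the grid cell of the final waypoint (None for external paths).
    """

    scenes: list[Scene]
    bearings_deg: np.ndarray
    cells: list[tuple[int, int] | None]
    end_cell: tuple[int, int] | None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.scenes:
            raise ValueError("training path must be non-empty")
        self.bearings_deg = np.asarray(self.bearings_deg, dtype=float) % 360.0

    def __len__(self) -> int:
        return len(self.scenes)

    @property
    def grid_cells(self) -> np.ndarray:
        """(k, 2) array of the on-grid cells (external scenes excluded)."""
        return np.array([c for c in self.cells if c is not None], dtype=float)


def bearing(p: Waypoint, q: Waypoint) -> float:
    """Compass bearing from p to q, degrees in [0, 360)."""
    dr, dc = q.row - p.row, q.col - p.col
    if dr == 0 and dc == 0:
        raise ValueError("coincident waypoints have no bearing")
    return math.degrees(math.atan2(dc, dr)) % 360.0


def _segment_cells(p: Waypoint, q: Waypoint,
                   shape: tuple[int, int]) -> list[tuple[int, int]]:
    """Supercover: every grid cell whose unit square the segment touches.

    Cell (i, j) occupies [i-1/2, i+1/2] x [j-1/2, j+1/2] around the grid
    node.  Intersection is computed exactly by segment-vs-AABB clipping
    (touching counts); cells are ordered by entry parameter along the
    segment, tie-broken by (row, col) for corner touches.
    """
    t, pmax = shape
    r0 = max(0, int(math.floor(min(p.row, q.row) - 0.5)))
    r1 = min(t - 1, int(math.ceil(max(p.row, q.row) + 0.5)))
    c0 = max(0, int(math.floor(min(p.col, q.col) - 0.5)))
    c1 = min(pmax - 1, int(math.ceil(max(p.col, q.col) + 0.5)))
    dr, dc = q.row - p.row, q.col - p.col
    hits: list[tuple[float, int, int]] = []
    for i in range(r0, r1 + 1):
        for j in range(c0, c1 + 1):
            tmin, tmax = 0.0, 1.0
            ok = True
            for start, delta, lo, hi in ((p.row, dr, i - 0.5, i + 0.5),
                                         (p.col, dc, j - 0.5, j + 0.5)):
                if delta == 0:
                    if start < lo or start > hi:
                        ok = False
                        break
                else:
                    ta, tb = (lo - start) / delta, (hi - start) / delta
                    if ta > tb:
                        ta, tb = tb, ta
                    tmin, tmax = max(tmin, ta), min(tmax, tb)
                    if tmin > tmax:
                        ok = False
                        break
            if ok:
                hits.append((tmin, i, j))
    hits.sort()
    return [(i, j) for _, i, j in hits]


def rasterize_path(landscape: GridLandscape, waypoints: list[Waypoint],
                   meta: dict | None = None) -> TrainingPath:
    """Build a training path from >= 2 waypoints over a survey grid.

    Each segment contributes the ordered supercover of grid cells it
    intersects; consecutive duplicates are dropped, so a cell at a segment
    junction keeps the earlier segment's bearing.  Each selected scene is
    rotated by its segment's bearing before storage.
    """
    if len(waypoints) < 2:
        raise ValueError("need at least 2 waypoints")
    t, p = landscape.shape
    for w in waypoints:
        if not (0 <= w.row <= t - 1 and 0 <= w.col <= p - 1):
            raise ValueError(f"waypoint {w} outside grid")
    cells: list[tuple[int, int]] = []
    bearings: list[float] = []
    for a, b in zip(waypoints[:-1], waypoints[1:]):
        if a == b:
            continue
        brg = bearing(a, b)
        for cell in _segment_cells(a, b, (t, p)):
            if cells and cells[-1] == cell:
                continue
            cells.append(cell)
            bearings.append(brg)
    if not cells:
        raise ValueError("waypoints are all coincident")
    scenes = [rotate_scene(landscape.scene(r, c), brg)
              for (r, c), brg in zip(cells, bearings)]
    last = waypoints[-1]
    end_cell = (int(round(last.row)), int(round(last.col)))
    return TrainingPath(scenes, np.array(bearings), list(cells), end_cell,
                        meta or {"waypoints": [(w.row, w.col) for w in waypoints]})


def ingest_novel_path(frames, resolution: int, gray_levels: int,
                      count: int = 50) -> TrainingPath:
    """Build a training path from externally captured raw frames.

    ``count`` evenly spaced frames (first and last always included) are
    preprocessed into scenes; bearings are unknown and stored as 0, with no
    grid cells.
    """
    frames = list(frames)
    if count < 2:
        raise ValueError("count must be >= 2")
    if count > len(frames):
        raise ValueError("fewer frames than requested count")
    idx = np.rint(np.linspace(0, len(frames) - 1, count)).astype(int)
    scenes = [preprocess(frames[i], resolution, gray_levels,
                         meta={"source_frame": int(i)}) for i in idx]
    return TrainingPath(scenes, np.zeros(count), [None] * count, None,
                        meta={"source": "external", "frame_indices": idx.tolist()})
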