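"""The scene-familiarity auto-tracking agent.

The agent sits on the survey grid, holds a compass heading, and repeatedly:

1. considers up to five adjacent captured views, in the fixed sequence
   front, 45° right, 45° left, 90° right, 90° left (a three-view variant
   stops after 45° left);
2. rotates each considered view through a full turn, comparing every
   rotation to all training-path scenes without regard to order;
3. moves to the first view whose minimum SAD beats the familiarity
   requirement — the mean landscape-to-path scene difference divided by the
   user threshold (>= 2) — or, if none does, to the overall best view; its
   best rotation angle becomes the new heading.

A run ends on reaching the path end (within a Chebyshev success radius,
default 2 points), exceeding the step budget, or oscillating back and forth
between two states.  Performance metrics: T, the total number of scenes
considered (a time proxy), and D, the cumulative distance in meters of the
visited cells from the nearest training-path cells (an accuracy proxy).

The algorithm is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .landscape import GridLandscape
from .path import TrainingPath
from .scene import best_rotation_match

__all__ = [
    "AgentState",
    "TrackerConfig",
    "StepRecord",
    "RecapResult",
    "required_familiarity",
    "familiarity_requirement",
    "considered_views",
    "step",
    "recapitulate",
]

# 8-neighborhood offsets by 45-degree compass sector (0 = +row, 90 = +col)
_SECTOR_OFFSETS = [(1, 0), (1, 1), (0, 1), (-1, 1), (-1, 0), (-1, -1),
                   (0, -1), (1, -1)]
_VIEW_OFFSETS = [("front", 0.0), ("45R", 45.0), ("45L", -45.0),
                 ("90R", 90.0), ("90L", -90.0)]


@dataclass(frozen=True)
class AgentState:
    cell: tuple[int, int]
    heading_deg: float = 0.0


@dataclass
class TrackerConfig:
    """User-set tracking parameters.

    ``threshold`` is the familiarity divisor (must be >= 2: higher demands a
    better match before the agent moves on).  ``view_set`` is "five-view" or
    "three-view".  ``requirement_mode`` selects how the mean scene
    difference behind the requirement is computed ("all-pairs" unrotated, or
    "rotation-minimized").
    """

    angle_step_deg: float = 1.0
    threshold: float = 4.0
    view_set: str = "five-view"
    max_steps: int = 200
    success_radius_points: int = 2
    oscillation_window: int = 8
    requirement_mode: str = "all-pairs"

    def __post_init__(self) -> None:
        if self.threshold < 2:
            raise ValueError("familiarity threshold must be 2 or higher")
        if self.view_set not in ("five-view", "three-view"):
            raise ValueError("view_set must be 'five-view' or 'three-view'")
        if self.angle_step_deg <= 0:
            raise ValueError("angle_step_deg must be positive")
        if self.max_steps < 1:
            raise ValueError("max_steps must be positive")
        if self.success_radius_points < 0:
            raise ValueError("success_radius_points must be >= 0")


@dataclass
class StepRecord:
    """Log of one step: every candidate actually evaluated, and the choice."""
    considered: list[dict]
    chosen: int                  # index into considered
    threshold_met: bool


@dataclass
class RecapResult:
    visited: list[AgentState]
    step_records: list[StepRecord]
    T: int                       # total scenes considered
    D: float                     # cumulative departure, meters
    success: bool
    termination: str             # reached-end | max-steps | oscillation | stuck


def required_familiarity(mean_difference: float, threshold: float) -> float:
    """The familiarity value a considered view must beat to allow movement.

    The threshold is a divisor of the mean scene difference: a mean of 1000
    with threshold 2 requires 500; threshold 4 requires 250.
    """
    if threshold < 2:
        raise ValueError("familiarity threshold must be 2 or higher")
    return float(mean_difference) / float(threshold)


def familiarity_requirement(landscape: GridLandscape, path: TrainingPath,
                            threshold: float, mode: str = "all-pairs",
                            angle_step: float = 1.0) -> float:
    """Requirement for a run: mean landscape-to-path SAD over threshold.

    "all-pairs" (default) averages the unrotated SAD over every (landscape
    scene, path scene) pair; "rotation-minimized" averages each landscape
    scene's best rotational match to the path instead.
    """
    if threshold < 2:
        raise ValueError("familiarity threshold must be 2 or higher")
    t, p = landscape.shape
    n = landscape.resolution
    flat = landscape.stack.reshape(t * p, n * n).astype(np.int32)
    mem = np.stack([s.matrix.ravel() for s in path.scenes]).astype(np.int32)
    if mode == "all-pairs":
        total = 0
        for i in range(mem.shape[0]):
            total += np.abs(flat - mem[i][None, :]).sum(dtype=np.int64)
        mean = total / (flat.shape[0] * mem.shape[0])
    elif mode == "rotation-minimized":
        mins = [best_rotation_match(landscape.scene(r, c), path.scenes,
                                    angle_step)[0]
                for r in range(t) for c in range(p)]
        mean = float(np.mean(mins))
    else:
        raise ValueError("mode must be 'all-pairs' or 'rotation-minimized'")
    return required_familiarity(mean, threshold)


def _sector(angle_deg: float) -> int:
    """Nearest 45-degree compass sector index (0-7)."""
    return int(round((angle_deg % 360.0) / 45.0)) % 8


def considered_views(state: AgentState, landscape: GridLandscape,
                     view_set: str = "five-view") -> list[dict]:
    """Candidate neighbor cells in the fixed view sequence.

    Each view offset is added to the heading, quantized to the nearest 45°
    sector and mapped to the corresponding 8-neighbor cell; off-grid
    candidates are dropped, order preserved.
    """
    t, p = landscape.shape
    r, c = state.cell
    if not (0 <= r < t and 0 <= c < p):
        raise IndexError("agent cell out of bounds")
    views = _VIEW_OFFSETS[:3] if view_set == "three-view" else _VIEW_OFFSETS
    out = []
    for label, off in views:
        sec = _sector(state.heading_deg + off)
        dr, dc = _SECTOR_OFFSETS[sec]
        cell = (r + dr, c + dc)
        if 0 <= cell[0] < t and 0 <= cell[1] < p:
            out.append({"view": label, "cell": cell, "sector": sec})
    return out


def step(state: AgentState, landscape: GridLandscape, path: TrainingPath,
         config: TrackerConfig, requirement: float
         ) -> tuple[AgentState | None, StepRecord | None]:
    """One decision cycle; returns (new state, record), or (None, None) if
    every candidate view is off-grid (a stuck corner)."""
    cands = considered_views(state, landscape, config.view_set)
    if not cands:
        return None, None
    records: list[dict] = []
    chosen = -1
    met = False
    for cand in cands:
        m, ang, idx = best_rotation_match(
            landscape.scene(*cand["cell"]), path.scenes, config.angle_step_deg)
        rec = dict(cand, min_sad=m, best_angle_deg=ang, best_memory_index=idx)
        records.append(rec)
        if m < requirement:       # first sub-requirement view wins outright;
            chosen = len(records) - 1  # later views are never evaluated
            met = True
            break
    if chosen < 0:
        sads = [r["min_sad"] for r in records]
        chosen = int(np.argmin(sads))  # ties -> earliest view order
    best = records[chosen]
    new = AgentState(best["cell"], float(best["best_angle_deg"]) % 360.0)
    return new, StepRecord(records, chosen, met)


def _departure(visited: list[AgentState], path: TrainingPath,
               spacing_m: float) -> float:
    cells = path.grid_cells
    if cells.size == 0:
        return 0.0
    total = 0.0
    for st in visited:
        d = np.hypot(cells[:, 0] - st.cell[0], cells[:, 1] - st.cell[1]).min()
        total += float(d) * spacing_m
    return total


def _oscillating(history: list[tuple[tuple[int, int], int]], window: int) -> bool:
    """True when the last ``window`` (cell, sector) states form a 2-cycle."""
    if window < 4 or len(history) < window:
        return False
    tail = history[-window:]
    if tail[0] == tail[1]:
        return False
    return all(tail[i] == tail[i % 2] for i in range(window))


def recapitulate(landscape: GridLandscape, path: TrainingPath,
                 start: AgentState, config: TrackerConfig,
                 requirement: float | None = None) -> RecapResult:
    """Run the agent from a start state until it reaches the path end,
    exhausts its step budget, or oscillates.

    Success means finishing within ``success_radius_points`` (Chebyshev) of
    the path's end cell; an oscillation inside that radius also counts (the
    agent has arrived and is merely rocking in place).
    """
    if path.end_cell is None:
        raise ValueError("path has no grid end cell")
    if requirement is None:
        requirement = familiarity_requirement(
            landscape, path, config.threshold, config.requirement_mode,
            config.angle_step_deg)
    end = path.end_cell
    rad = config.success_radius_points
    state = start
    visited = [state]
    records: list[StepRecord] = []
    history = [(state.cell, _sector(state.heading_deg))]
    total = 0
    success = False
    termination = "max-steps"

    def at_end(s: AgentState) -> bool:
        return max(abs(s.cell[0] - end[0]), abs(s.cell[1] - end[1])) <= rad

    for _ in range(config.max_steps):
        if at_end(state):
            success = True
            termination = "reached-end"
            break
        new, rec = step(state, landscape, path, config, requirement)
        if new is None:
            termination = "stuck"
            break
        records.append(rec)
        total += len(rec.considered)
        state = new
        visited.append(state)
        history.append((state.cell, _sector(state.heading_deg)))
        if _oscillating(history, config.oscillation_window):
            termination = "oscillation"
            success = at_end(state)
            break
    else:
        success = at_end(state)
        termination = "reached-end" if success else "max-steps"

    d = _departure(visited, path, landscape.spacing_m)
    return RecapResult(visited, records, total, d, success, termination)
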