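"""Perceptual-aliasing analysis of linear traverses.

Repetitive corridors produce scenes that resemble scenes some distance away
along the path — a hazard for familiarity-based navigation.  This module
computes the unrotated cross-SAD matrix of an ordered scene sequence, the
mean +/- SD difference profile over the nearest scenes around each focal
scene (signed offsets -12..+12 for the default 25-scene window), detects
local minima in that profile, and summarizes the aliasing hazard as a
single index: the lowest local-minimum value minus the nearest-scene value.
A larger index means a lower probability of aliasing; a sequence with no
local minima (a visually rich setting) has no index at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .scene import Scene, sad

__all__ = [
    "SceneSequence",
    "AliasingProfile",
    "cross_sad_matrix",
    "neighborhood_profile",
    "find_local_minima",
    "aliasing_index",
    "analyze_sequence",
    "rank_neighbors",
]


@dataclass
class SceneSequence:
    """Ordered scenes along one linear traverse (default capture is 50)."""

    scenes: list[Scene]
    setting: str = ""

    def __post_init__(self) -> None:
        if len(self.scenes) < 5:
            raise ValueError("a sequence needs at least 5 scenes")
        n = self.scenes[0].resolution
        g = self.scenes[0].gray_levels
        if any(s.resolution != n or s.gray_levels != g for s in self.scenes):
            raise ValueError("scenes must share resolution and gray depth")

    def __len__(self) -> int:
        return len(self.scenes)


@dataclass
class AliasingProfile:
    sad_matrix: np.ndarray       # (n, n) symmetric, zero diagonal
    offsets: np.ndarray          # signed, -k..+k
    mean_curve: np.ndarray
    sd_curve: np.ndarray
    local_minima: list[tuple[int, float]]
    index: float | None
    setting: str = ""


def cross_sad_matrix(seq: SceneSequence) -> np.ndarray:
    """Unrotated SAD of every scene pair; symmetric with zero diagonal."""
    flat = np.stack([s.matrix.ravel() for s in seq.scenes]).astype(np.int32)
    d = np.abs(flat[:, None, :] - flat[None, :, :]).sum(axis=2, dtype=np.int64)
    return d


def neighborhood_profile(matrix: np.ndarray,
                         window: int = 25) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean and SD of SAD at each signed offset within the nearest window.

    For offsets o in -(window-1)/2 .. +(window-1)/2, pools matrix[i, i+o]
    over every focal i with i+o in range (the window truncates at the
    sequence ends).  Returns (offsets, mean, sd); SD is the sample standard
    deviation (0 where only one value contributes).
    """
    n = matrix.shape[0]
    if window % 2 == 0 or window > n:
        raise ValueError("window must be odd and <= sequence length")
    half = (window - 1) // 2
    offsets = np.arange(-half, half + 1)
    mean = np.empty(offsets.size)
    sd = np.empty(offsets.size)
    for k, o in enumerate(offsets):
        i = np.arange(max(0, -o), min(n, n - o))
        vals = matrix[i, i + o].astype(float)
        mean[k] = vals.mean()
        sd[k] = vals.std(ddof=1) if vals.size > 1 else 0.0
    return offsets, mean, sd


def find_local_minima(offsets: np.ndarray,
                      mean_curve: np.ndarray) -> list[tuple[int, float]]:
    """Offsets with |o| >= 2 where the mean curve dips strictly below both
    neighbors."""
    out = []
    for k in range(1, offsets.size - 1):
        o = int(offsets[k])
        if abs(o) < 2:
            continue
        if mean_curve[k] < mean_curve[k - 1] and mean_curve[k] < mean_curve[k + 1]:
            out.append((o, float(mean_curve[k])))
    return out


def aliasing_index(profile: AliasingProfile) -> float | None:
    """Lowest local-minimum value minus the nearest-scene value, or None.

    The nearest-scene value is the mean of the curve at offsets -1 and +1.
    Larger values mean a lower probability of aliasing; a curve with no
    local minimum (monotone away from the focal scene) yields None.
    """
    if not profile.local_minima:
        return None
    k = profile.offsets.tolist()
    nearest = 0.5 * (profile.mean_curve[k.index(-1)] + profile.mean_curve[k.index(1)])
    lowest = min(v for _, v in profile.local_minima)
    return float(lowest - nearest)


def analyze_sequence(seq: SceneSequence, window: int = 25) -> AliasingProfile:
    """Full aliasing analysis of one traverse."""
    m = cross_sad_matrix(seq)
    offsets, mean, sd = neighborhood_profile(m, window)
    minima = find_local_minima(offsets, mean)
    prof = AliasingProfile(m, offsets, mean, sd, minima, None, seq.setting)
    prof.index = aliasing_index(prof)
    return prof


def rank_neighbors(stack: list[Scene], focal: int, k: int = 8,
                   settings: list[str] | None = None,
                   positions: list[int] | None = None,
                   radius: int = 1) -> dict:
    """Rank all scenes in a multi-setting stack by SAD to a focal scene.

    Rank 0 is the focal itself (SAD 0).  The report lists the k most
    similar non-focal scenes and, when setting labels and within-setting
    positions are given, whether each lies within ``radius`` positions of
    the focal in the focal's own setting — i.e. whether the match is a true
    path neighbor or a potential alias.
    """
    if len(stack) < k + 1:
        raise ValueError("stack must hold at least k + 1 scenes")
    if not (0 <= focal < len(stack)):
        raise IndexError("focal index out of range")
    f = stack[focal]
    sads = np.array([sad(f, s) for s in stack], dtype=np.int64)
    others = [i for i in range(len(stack)) if i != focal]
    others.sort(key=lambda i: (sads[i], i))
    ranked = [focal] + others
    report = []
    for i in others[:k]:
        entry = {"index": i, "sad": int(sads[i])}
        if settings is not None and positions is not None:
            entry["setting"] = settings[i]
            entry["adjacent"] = (settings[i] == settings[focal]
                                 and abs(positions[i] - positions[focal]) <= radius)
        report.append(entry)
    return {"ranked_indices": ranked, "sads": sads, "neighbors": report}
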