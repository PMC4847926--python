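"""Persistence and export plumbing: PNG scene stores, JSON manifests, CSV
exports, and static plot rendering.

Scenes are stored as 8-bit grayscale PNGs (stored value = level *
floor(255 / (G - 1))) beside a JSON manifest recording resolution, gray
depth, mask and angle conventions, and provenance, so every artifact is
inspectable and re-ingestable.  All angles are degrees, all distances
meters; the conventions are repeated in every manifest to prevent drift.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import __version__
from .aliasing import AliasingProfile, SceneSequence
from .landscape import (DifferenceField, GridLandscape, IDFSummary,
                        QuiverField, RIDFSummary)
from .path import TrainingPath
from .scene import (EQUALIZATION, MASK_CONVENTION, ROTATION_CONVENTION,
                    Scene, apply_mask)
from .tracker import RecapResult

__all__ = [
    "write_scene_png", "read_scene_png",
    "write_landscape", "read_landscape",
    "write_training_path", "read_training_path",
    "write_sequence", "read_sequence",
    "field_to_csv", "idf_to_csv", "ridf_to_csv", "matrix_to_csv",
    "profile_to_json", "recap_to_json",
    "plot_field", "plot_quiver", "plot_curve", "plot_trajectory",
]

CONVENTIONS = {
    "mask": MASK_CONVENTION,
    "rotation": ROTATION_CONVENTION,
    "equalization": EQUALIZATION,
    "compass": "0 deg = +row (transect axis), 90 deg = +col (point axis)",
    "angles": "degrees",
    "distances": "meters",
}


def _manifest(extra: dict) -> dict:
    return {"tool": "scenefam", "version": __version__,
            "conventions": CONVENTIONS, **extra}


def _png_step(gray_levels: int) -> int:
    if not 2 <= gray_levels <= 256:
        raise ValueError("PNG store supports 2..256 gray levels")
    return 255 // (gray_levels - 1)


def write_scene_png(scene: Scene, path: str | Path,
                    sidecar: bool = True) -> None:
    """Write a scene as an 8-bit grayscale PNG plus a sidecar JSON."""
    path = Path(path)
    step = _png_step(scene.gray_levels)
    img = (scene.matrix.astype(np.uint16) * step).astype(np.uint8)
    Image.fromarray(img, mode="L").save(path)
    if sidecar:
        meta = {k: v for k, v in scene.meta.items()}
        path.with_suffix(".json").write_text(json.dumps(_manifest({
            "resolution": scene.resolution,
            "gray_levels": scene.gray_levels,
            "level_step": step,
            "meta": meta,
        }), indent=1, default=str))


def read_scene_png(path: str | Path, gray_levels: int | None = None) -> Scene:
    """Read a scene PNG; gray depth comes from the sidecar unless given."""
    path = Path(path)
    meta: dict = {}
    if gray_levels is None:
        side = json.loads(path.with_suffix(".json").read_text())
        gray_levels = side["gray_levels"]
        meta = side.get("meta", {})
    step = _png_step(gray_levels)
    arr = np.asarray(Image.open(path).convert("L"), dtype=np.int16) // step
    return Scene(apply_mask(np.clip(arr, 0, gray_levels - 1)), gray_levels, meta)


def _scene_name(r: int, c: int) -> str:
    return f"r{r:03d}_c{c:03d}.png"


def write_landscape(landscape: GridLandscape, out_dir: str | Path) -> None:
    """Persist a survey grid as one PNG per cell plus manifest.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t, p = landscape.shape
    for r in range(t):
        for c in range(p):
            write_scene_png(landscape.scene(r, c), out / _scene_name(r, c),
                            sidecar=False)
    (out / "manifest.json").write_text(json.dumps(_manifest({
        "kind": "landscape",
        "transects": t, "points": p,
        "resolution": landscape.resolution,
        "gray_levels": landscape.gray_levels,
        "spacing_m": landscape.spacing_m,
        "meta": landscape.meta,
    }), indent=1, default=str))


def read_landscape(in_dir: str | Path) -> GridLandscape:
    src = Path(in_dir)
    man = json.loads((src / "manifest.json").read_text())
    t, p, g = man["transects"], man["points"], man["gray_levels"]
    n = man["resolution"]
    stack = np.empty((t, p, n, n), dtype=np.int16)
    for r in range(t):
        for c in range(p):
            stack[r, c] = read_scene_png(src / _scene_name(r, c), g).matrix
    return GridLandscape(stack, g, man["spacing_m"], man.get("meta", {}))


def write_training_path(path_obj: TrainingPath, out_dir: str | Path) -> None:
    """Persist a training path: rotated scene PNGs plus path.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, s in enumerate(path_obj.scenes):
        write_scene_png(s, out / f"scene{i:04d}.png", sidecar=False)
    (out / "path.json").write_text(json.dumps(_manifest({
        "kind": "training-path",
        "count": len(path_obj),
        "resolution": path_obj.scenes[0].resolution,
        "gray_levels": path_obj.scenes[0].gray_levels,
        "bearings_deg": path_obj.bearings_deg.tolist(),
        "cells": [list(c) if c is not None else None for c in path_obj.cells],
        "end_cell": list(path_obj.end_cell) if path_obj.end_cell else None,
        "meta": path_obj.meta,
    }), indent=1, default=str))


def read_training_path(in_dir: str | Path) -> TrainingPath:
    src = Path(in_dir)
    man = json.loads((src / "path.json").read_text())
    g = man["gray_levels"]
    scenes = [read_scene_png(src / f"scene{i:04d}.png", g)
              for i in range(man["count"])]
    cells = [tuple(c) if c is not None else None for c in man["cells"]]
    end = tuple(man["end_cell"]) if man["end_cell"] else None
    return TrainingPath(scenes, np.array(man["bearings_deg"]), cells, end,
                        man.get("meta", {}))


def write_sequence(seq: SceneSequence, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, s in enumerate(seq.scenes):
        write_scene_png(s, out / f"frame{i:04d}.png", sidecar=False)
    (out / "sequence.json").write_text(json.dumps(_manifest({
        "kind": "traverse",
        "count": len(seq),
        "resolution": seq.scenes[0].resolution,
        "gray_levels": seq.scenes[0].gray_levels,
        "setting": seq.setting,
    }), indent=1, default=str))


def read_sequence(in_dir: str | Path) -> SceneSequence:
    src = Path(in_dir)
    man = json.loads((src / "sequence.json").read_text())
    g = man["gray_levels"]
    scenes = [read_scene_png(src / f"frame{i:04d}.png", g)
              for i in range(man["count"])]
    return SceneSequence(scenes, man.get("setting", ""))


# ---------------------------------------------------------------- CSV / JSON

def field_to_csv(fieldobj: DifferenceField | QuiverField,
                 out_csv: str | Path) -> None:
    """One row per grid cell."""
    if isinstance(fieldobj, QuiverField):
        t, p = fieldobj.best_angle_deg.shape
        rows = [{"row": r, "col": c,
                 "best_angle_deg": fieldobj.best_angle_deg[r, c],
                 "strength": fieldobj.strength[r, c]}
                for r in range(t) for c in range(p)]
    else:
        t, p = fieldobj.values.shape
        rows = [{"row": r, "col": c, "value": fieldobj.values[r, c],
                 "kind": fieldobj.kind}
                for r in range(t) for c in range(p)]
    pd.DataFrame(rows).to_csv(out_csv, index=False)


def idf_to_csv(summary: IDFSummary, out_csv: str | Path) -> None:
    pd.DataFrame({"distance_m": summary.distances_m,
                  "mean_norm_diff": summary.mean_norm_diff,
                  "count": summary.counts}).to_csv(out_csv, index=False)


def ridf_to_csv(summary: RIDFSummary, out_csv: str | Path) -> None:
    pd.DataFrame({"angle_deg": summary.angles_deg,
                  "mean_norm_diff": summary.mean_norm_diff}).to_csv(
        out_csv, index=False)


def matrix_to_csv(matrix: np.ndarray, out_csv: str | Path) -> None:
    pd.DataFrame(matrix).to_csv(out_csv, index=False, header=False)


def profile_to_json(profile: AliasingProfile, out_json: str | Path) -> None:
    Path(out_json).write_text(json.dumps(_manifest({
        "kind": "aliasing-profile",
        "setting": profile.setting,
        "offsets": profile.offsets.tolist(),
        "mean_curve": profile.mean_curve.tolist(),
        "sd_curve": profile.sd_curve.tolist(),
        "local_minima": [[int(o), v] for o, v in profile.local_minima],
        "index": profile.index,
    }), indent=1))


def recap_to_json(result: RecapResult, out_json: str | Path,
                  params: dict | None = None) -> None:
    Path(out_json).write_text(json.dumps(_manifest({
        "kind": "recapitulation",
        "params": params or {},
        "visited": [{"cell": list(s.cell), "heading_deg": s.heading_deg}
                    for s in result.visited],
        "steps": [{
            "considered": [{k: (list(v) if isinstance(v, tuple) else v)
                            for k, v in c.items()} for c in rec.considered],
            "chosen": rec.chosen,
            "threshold_met": rec.threshold_met,
        } for rec in result.step_records],
        "T": result.T,
        "D_m": result.D,
        "success": result.success,
        "termination": result.termination,
    }), indent=1))


# ------------------------------------------------------------------- plots

def _save(fig, out_path: str | Path) -> None:
    fig.savefig(out_path, dpi=150, bbox_inches="tight")
    import matplotlib.pyplot as plt
    plt.close(fig)


def plot_field(fieldobj: DifferenceField, out_path: str | Path,
               title: str = "", contour: bool = False) -> None:
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots()
    if contour:
        ax.contourf(fieldobj.values, levels=12, cmap="viridis")
    else:
        im = ax.imshow(fieldobj.values, cmap="viridis", origin="lower")
        fig.colorbar(im, ax=ax, label="abs. scene diff.")
    ax.set_xlabel("point")
    ax.set_ylabel("transect")
    ax.set_title(title)
    _save(fig, out_path)


def plot_quiver(q: QuiverField, out_path: str | Path, title: str = "") -> None:
    import matplotlib.pyplot as plt
    t, p = q.best_angle_deg.shape
    rows, cols = np.mgrid[0:t, 0:p]
    a = np.radians(q.best_angle_deg)
    # compass 0 = +row: quiver u along columns (x), v along rows (y)
    u = q.strength * np.sin(a)
    v = q.strength * np.cos(a)
    fig, ax = plt.subplots()
    ax.quiver(cols, rows, u, v, color="red", scale=25)
    ax.set_xlabel("point")
    ax.set_ylabel("transect")
    ax.set_title(title)
    _save(fig, out_path)


def plot_curve(x: np.ndarray, y: np.ndarray, out_path: str | Path,
               xlabel: str = "", ylabel: str = "", title: str = "",
               sd: np.ndarray | None = None) -> None:
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots()
    ax.plot(x, y, "-o", ms=3)
    if sd is not None:
        ax.fill_between(x, y - sd, y + sd, alpha=0.25)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.set_title(title)
    _save(fig, out_path)


def plot_trajectory(result: RecapResult, path_obj: TrainingPath,
                    shape: tuple[int, int], out_path: str | Path,
                    title: str = "") -> None:
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots()
    cells = path_obj.grid_cells
    if cells.size:
        ax.plot(cells[:, 1], cells[:, 0], "b-", lw=2, label="training path")
    rr = [s.cell[0] for s in result.visited]
    cc = [s.cell[1] for s in result.visited]
    ax.plot(cc, rr, "r.-", label="agent")
    ax.plot(cc[0], rr[0], "ko", label="start")
    ax.set_xlim(-0.5, shape[1] - 0.5)
    ax.set_ylim(-0.5, shape[0] - 0.5)
    ax.set_xlabel("point")
    ax.set_ylabel("transect")
    ax.legend(loc="best", fontsize=8)
    ax.set_title(title)
    _save(fig, out_path)
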