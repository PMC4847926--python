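"""Procedural synthetic survey worlds rendered through a fisheye camera.

Stands in for the physical laboratory survey: a rectangular room whose wall
and ceiling features are imaged by an upward-looking omnidirectional camera
on a regular grid of positions.  Landmarks are Gaussian gray splats placed
on the walls and ceiling; an equidistant fisheye projection (image radius
proportional to the polar angle from the zenith) maps them into the circular
image.  All randomness is fixed by the world seed.

World frame: x along the +row (transect) axis = compass 0°, y along the
+column (point) axis = compass 90°, z up.  A scene rendered at heading h
shows a landmark at compass bearing b at image azimuth b - h, matching
:func:`scenefam.scene.rotate_scene`'s clockwise convention.

Scenes are evaluated on a supersampled pixel grid (about 100 px across by
default) and block-averaged down to the sensor resolution before
quantization, emulating a capture-then-pixelate pipeline; low-resolution
sensors therefore see a genuinely blurred world, which is what gives them
their wider catchment areas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .scene import Scene, _rot_coeffs, apply_mask, circular_mask, quantize

__all__ = [
    "Landmark",
    "WorldSpec",
    "RenderConfig",
    "rich_world",
    "corridor_world",
    "render_scene",
    "generate_landscape",
    "generate_traverse",
]

BACKGROUND_GRAY = 0.5


@dataclass
class Landmark:
    position: tuple[float, float, float]  # meters, world frame
    gray: float                            # [0, 1]
    angular_size_deg: float                # full angular width of the splat


@dataclass
class WorldSpec:
    """A rectangular room populated with visual landmarks.

    ``periodicity`` (meters), when set, marks a corridor world whose motif
    repeats at that distance along x.
    """

    room_size_m: tuple[float, float, float]
    landmarks: list[Landmark]
    richness: float = 1.0
    periodicity: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.room_size_m):
            raise ValueError("room dimensions must be positive")
        lx, ly, lz = self.room_size_m
        for lm in self.landmarks:
            x, y, z = lm.position
            if not (0 <= x <= lx and 0 <= y <= ly and 0 <= z <= lz):
                raise ValueError("landmark outside room")


@dataclass
class RenderConfig:
    """Camera and sensor parameters.

    ``camera_height_m`` defaults to 1.28 m (the survey lens height);
    ``base_resolution`` sets the supersampled capture grid that is averaged
    down to ``resolution``.
    """

    resolution: int = 100
    gray_levels: int = 10
    camera_height_m: float = 1.28
    base_resolution: int = 100

    def __post_init__(self) -> None:
        if self.resolution < 5:
            raise ValueError("resolution must be >= 5")
        if self.gray_levels < 2:
            raise ValueError("gray_levels must be >= 2")

    def supersample(self) -> int:
        return max(1, round(self.base_resolution / self.resolution))


def _wall_landmarks(rng: np.random.Generator, room: tuple[float, float, float],
                    count: int, x_range: tuple[float, float] | None = None) -> list[Landmark]:
    lx, ly, lz = room
    x_lo, x_hi = x_range if x_range else (0.0, lx)
    lms: list[Landmark] = []
    for _ in range(count):
        face = rng.integers(0, 5)
        x = rng.uniform(x_lo, x_hi)
        y = rng.uniform(0, ly)
        z = rng.uniform(1.4, lz)  # above typical camera height
        if face == 0:
            pos = (x, 0.0, z)
        elif face == 1:
            pos = (x, ly, z)
        elif face == 2:
            pos = (x_lo, y, z)
        elif face == 3:
            pos = (x_hi if x_hi <= lx else lx, y, z)
        else:
            pos = (x, y, lz)  # ceiling
        # multi-scale features: mostly fine texture, some large furniture
        if rng.uniform() < 0.6:
            size = float(rng.uniform(2.5, 10.0))
        else:
            size = float(rng.uniform(10.0, 30.0))
        lms.append(Landmark(pos, float(rng.uniform(0.0, 1.0)), size))
    return lms


def rich_world(seed: int = 0, room_size_m: tuple[float, float, float] = (5.1, 5.7, 3.0),
               richness: float = 1.0) -> WorldSpec:
    """A visually rich, aperiodic room.

    Room defaults approximate a 40 x 45 survey at 12.7-cm pitch; richness
    scales the landmark count (1.0 -> 120 landmarks).
    """
    if not 0.0 <= richness <= 1.0:
        raise ValueError("richness must be in [0, 1]")
    rng = np.random.default_rng(seed)
    count = max(8, int(round(120 * richness)))
    lms = _wall_landmarks(rng, room_size_m, count)
    return WorldSpec(room_size_m, lms, richness=richness, seed=seed)


def corridor_world(seed: int = 0, length_m: float = 16.0, width_m: float = 2.5,
                   height_m: float = 3.0, period_m: float | None = None,
                   motif_size: int = 10) -> WorldSpec:
    """A long corridor; with ``period_m`` set, one landmark motif tiles along
    its length to force repetitive scenery (perceptual aliasing)."""
    rng = np.random.default_rng(seed)
    room = (length_m, width_m, height_m)
    if period_m is None:
        lms = _wall_landmarks(rng, room, 3 * motif_size)
        return WorldSpec(room, lms, seed=seed)
    if period_m <= 0 or period_m > length_m:
        raise ValueError("period must be in (0, corridor length]")
    motif = _wall_landmarks(rng, room, motif_size, x_range=(0.0, period_m))
    lms: list[Landmark] = []
    reps = int(math.floor(length_m / period_m + 1e-9))
    for k in range(reps):
        for lm in motif:
            x, y, z = lm.position
            xk = x + k * period_m
            if xk <= length_m:
                lms.append(Landmark((xk, y, z), lm.gray, lm.angular_size_deg))
    return WorldSpec(room, lms, periodicity=period_m, seed=seed)


def _render_field(world: WorldSpec, position: tuple[float, float],
                  heading_deg: float, config: RenderConfig) -> np.ndarray:
    """Continuous gray field sampled on the supersampled pixel grid."""
    n = config.resolution
    s = config.supersample()
    nf = n * s
    c = (nf - 1) / 2.0
    d = np.arange(nf) - c
    dr = np.broadcast_to(d[:, None], (nf, nf))
    dc = np.broadcast_to(d[None, :], (nf, nf))
    # rotate pixel offsets by +heading: pixel at azimuth a views bearing a+h
    cosa, sina = _rot_coeffs(heading_deg)
    pr = dr * cosa - dc * sina
    pc = dr * sina + dc * cosa
    # normalized image-plane coordinates (radius 1 at the rim)
    u = pr / (nf / 2.0)
    v = pc / (nf / 2.0)

    x0, y0 = position
    z0 = config.camera_height_m
    img = np.full((nf, nf), BACKGROUND_GRAY)
    order = sorted(
        range(len(world.landmarks)),
        key=lambda i: -math.dist((x0, y0, z0), world.landmarks[i].position),
    )
    for i in order:  # far-to-near compositing
        lm = world.landmarks[i]
        dx = lm.position[0] - x0
        dy = lm.position[1] - y0
        dz = lm.position[2] - z0
        dist = math.sqrt(dx * dx + dy * dy + dz * dz)
        if dist == 0 or dz <= 0:
            continue  # at or below the camera: outside the upward hemisphere
        psi = math.acos(min(1.0, dz / dist))  # polar angle from zenith
        rho = psi / (math.pi / 2.0)           # equidistant projection
        if rho > 1.2:
            continue
        b = math.atan2(dy, dx)
        cu = rho * math.cos(b)
        cv = rho * math.sin(b)
        sigma = (lm.angular_size_deg / 2.0) / 90.0
        d2 = (u - cu) ** 2 + (v - cv) ** 2
        wgt = np.exp(-d2 / (2.0 * sigma * sigma))
        img = img * (1.0 - wgt) + lm.gray * wgt
    if s > 1:
        img = img.reshape(n, s, n, s).mean(axis=(1, 3))
    return img


def render_scene(world: WorldSpec, position: tuple[float, float],
                 heading_deg: float, config: RenderConfig,
                 meta: dict | None = None) -> Scene:
    """Render one panoramic snapshot at a camera position and heading."""
    lx, ly, _ = world.room_size_m
    x, y = position
    if not (0 <= x <= lx and 0 <= y <= ly):
        raise ValueError("camera position outside room")
    img = _render_field(world, position, heading_deg, config)
    levels = quantize(np.clip(img, 0.0, 1.0), config.gray_levels)
    m = dict(meta or {})
    m.setdefault("heading_deg", float(heading_deg % 360.0))
    m.setdefault("position_m", (float(x), float(y)))
    return Scene(apply_mask(levels), config.gray_levels, m)


def generate_landscape(world: WorldSpec, transects: int = 40, points: int = 45,
                       spacing_m: float = 0.127,
                       config: RenderConfig | None = None):
    """Render a T x P survey grid at heading 0, centered in the room.

    The default 40 x 45 grid at 12.7-cm centers yields 1800 scenes.
    Returns a :class:`scenefam.landscape.GridLandscape`.
    """
    from .landscape import GridLandscape

    config = config or RenderConfig()
    if transects < 1 or points < 1 or spacing_m <= 0:
        raise ValueError("invalid grid shape or spacing")
    lx, ly, _ = world.room_size_m
    ext_x = (transects - 1) * spacing_m
    ext_y = (points - 1) * spacing_m
    if ext_x > lx or ext_y > ly:
        raise ValueError("survey grid does not fit in the room")
    x0 = (lx - ext_x) / 2.0
    y0 = (ly - ext_y) / 2.0
    stack = np.empty((transects, points, config.resolution, config.resolution),
                     dtype=np.int16)
    for r in range(transects):
        for c in range(points):
            sc = render_scene(world, (x0 + r * spacing_m, y0 + c * spacing_m),
                              0.0, config, meta={"row": r, "col": c})
            stack[r, c] = sc.matrix
    return GridLandscape(stack, config.gray_levels, spacing_m,
                         meta={"seed": world.seed, "origin_m": (x0, y0),
                               "heading_deg": 0.0})


def generate_traverse(world: WorldSpec, start: tuple[float, float],
                      end: tuple[float, float], n: int = 50,
                      config: RenderConfig | None = None, setting: str = ""):
    """Render ``n`` evenly spaced scenes along a straight traverse.

    Headings are fixed along the traverse direction (compass of end-start).
    Returns a :class:`scenefam.aliasing.SceneSequence`.
    """
    from .aliasing import SceneSequence

    config = config or RenderConfig(gray_levels=100)
    if n < 5:
        raise ValueError("a traverse needs at least 5 scenes")
    if start == end:
        raise ValueError("degenerate traverse: start equals end")
    heading = math.degrees(math.atan2(end[1] - start[1], end[0] - start[0])) % 360.0
    xs = np.linspace(start[0], end[0], n)
    ys = np.linspace(start[1], end[1], n)
    scenes = [render_scene(world, (float(x), float(y)), heading, config,
                           meta={"index": i})
              for i, (x, y) in enumerate(zip(xs, ys))]
    return SceneSequence(scenes, setting=setting or f"traverse-seed{world.seed}")
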