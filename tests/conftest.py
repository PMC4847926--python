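import numpy as np
import pytest

import scenefam as sf


def random_scene(rng: np.random.Generator, n: int = 12, g: int = 10) -> sf.Scene:
    """A valid random scene: quantized levels, circularly masked."""
    m = rng.integers(0, g, size=(n, n)).astype(np.int16)
    m[~np.asarray(sf.circular_mask(n))] = 0
    return sf.Scene(m, g)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def small_world():
    return sf.rich_world(seed=7)


@pytest.fixture(scope="session")
def small_landscape(small_world):
    """6 x 6 survey grid at N=16, G=10 in a rich seeded room."""
    cfg = sf.RenderConfig(resolution=16, gray_levels=10)
    return sf.generate_landscape(small_world, 6, 6, 0.127, cfg)


@pytest.fixture(scope="session")
def straight_path(small_landscape):
    return sf.rasterize_path(small_landscape,
                             [sf.Waypoint(1, 0), sf.Waypoint(1, 5)])


def identical_landscape(scene: sf.Scene, t: int, p: int,
                        spacing: float = 0.127) -> sf.GridLandscape:
    stack = np.broadcast_to(scene.matrix, (t, p) + scene.matrix.shape).copy()
    return sf.GridLandscape(stack, scene.gray_levels, spacing)
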