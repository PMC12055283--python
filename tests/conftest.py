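import numpy as np
import pytest

from leafsettle.geometry import Outline, normalize_area, resample_outline
from leafsettle.shapegen import RandomWalkConfig, random_walk_shape


@pytest.fixture
def unit_square() -> Outline:
    return Outline([(0, 0), (1, 0), (1, 1), (0, 1)], label="square")


@pytest.fixture
def scalene_triangle() -> Outline:
    return Outline([(0, 0), (4, 0), (0, 2)], label="triangle")


@pytest.fixture
def plus_sign() -> Outline:
    # two 1x3 rectangles crossed at centre: area 5, hull area 7
    return Outline(
        [(1, 0), (2, 0), (2, 1), (3, 1), (3, 2), (2, 2), (2, 3), (1, 3), (1, 2),
         (0, 2), (0, 1), (1, 1)],
        label="plus",
    )


@pytest.fixture
def disc_256() -> Outline:
    th = np.linspace(0, 2 * np.pi, 256, endpoint=False)
    return Outline(np.column_stack([np.cos(th), np.sin(th)]), label="disc")


@pytest.fixture
def disc_100mm2(disc_256) -> Outline:
    return normalize_area(resample_outline(disc_256, 512))


def random_blob(seed: int, n: int = 512) -> Outline:
    """Star-shaped random outline: cheap, always simple, asymmetric."""
    rng = np.random.default_rng(seed)
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    r = np.ones_like(th)
    for k in range(1, 7):
        r += rng.uniform(-0.4, 0.4) / k * np.cos(k * th + rng.uniform(0, 2 * np.pi))
    r = np.clip(r, 0.2, None)
    return Outline(np.column_stack([r * np.cos(th), r * np.sin(th)]),
                   label=f"blob{seed}")


@pytest.fixture(scope="session")
def random_walk_batch() -> list[Outline]:
    """A batch of diffusing-particle outlines shared across tests."""
    return [random_walk_shape(RandomWalkConfig(seed=s)) for s in range(12)]
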