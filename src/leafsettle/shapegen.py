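"""Comparison shape sets: random-walk blobs, ideal forms, parametric leaves.

Three seeded generators populate the symmetry-lobedness plane around the
extant-leaf cluster:

* :func:`random_walk_shape` — the outline of a thickened diffusing-particle
  path: irregular, typically asymmetric blobs spanning low-to-mid S.
* :func:`ideal_forms` — ten mirror-symmetric reference shapes (disc,
  regular polygons, ellipses, a stadium), all with S = 1.
* :func:`parametric_leaf` — a radial harmonic family with independent
  knobs for lobe count/depth (drives L) and mirror-symmetry breaking
  (drives S), used as a controllable test fixture.

All generators are pure functions of their configs (same seed, same
outline) and emit simple polygons at 512 vertices, normalized to the study
blade area of 100 mm².
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from shapely.geometry import LineString

from .geometry import (
    DEFAULT_RESOLUTION,
    InvalidOutlineError,
    Outline,
    normalize_area,
    resample_outline,
)

__all__ = [
    "RandomWalkConfig",
    "ParametricLeafConfig",
    "ShapeGenerationError",
    "random_walk_shape",
    "ideal_forms",
    "parametric_leaf",
]


class ShapeGenerationError(RuntimeError):
    """No valid simple outline could be produced from the configuration."""


@dataclass(frozen=True)
class RandomWalkConfig:
    """Diffusing-particle outline generator parameters.

    A 2-D Gaussian random walk of ``n_steps`` steps (per-axis step sd
    ``step_sigma`` mm) is thickened to a ribbon of width ``path_width`` mm;
    the outer boundary of the ribbon is the generated shape, smoothed with
    a circular moving average of ``smoothing_window`` vertices so the
    outline stays laser-cuttable (bounded curvature).
    """

    seed: int = 0
    n_steps: int = 2000
    step_sigma: float = 0.5
    path_width: float = 1.0
    smoothing_window: int = 9

    def __post_init__(self) -> None:
        if self.n_steps < 100:
            raise ValueError("n_steps must be >= 100")
        if not self.path_width > 0:
            raise ValueError("path_width must be > 0")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be a positive odd integer")


@dataclass(frozen=True)
class ParametricLeafConfig:
    """Radial harmonic leaf family with independent lobedness/asymmetry.

    r(theta) is a base ellipse of the given aspect ratio, modulated by
    ``lobe_depth * cos(lobe_count * theta)`` (mirror-symmetric lobes) plus
    sine harmonics of order 2 and 3 scaled by ``asymmetry``.  Those two
    sine harmonics admit no common mirror axis (their axis sets
    pi/4 + m pi/2 and pi/6 + m pi/3 never meet), so asymmetry = 0
    guarantees a mirror axis and asymmetry > 0 destroys all of them.
    """

    lobe_count: int = 5
    lobe_depth: float = 0.0
    asymmetry: float = 0.0
    aspect_ratio: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lobe_count < 0:
            raise ValueError("lobe_count must be >= 0")
        if not 0.0 <= self.lobe_depth < 1.0:
            raise ValueError("lobe_depth must be in [0, 1)")
        if not 0.0 <= self.asymmetry < 1.0:
            raise ValueError("asymmetry must be in [0, 1)")
        if not self.aspect_ratio > 0:
            raise ValueError("aspect_ratio must be > 0")


def _smooth_closed(vertices: np.ndarray, window: int) -> np.ndarray:
    """Circular moving average of the vertex coordinates."""
    if window <= 1:
        return vertices
    kernel = np.ones(window) / window
    pad = window // 2
    out = np.empty_like(vertices)
    for j in range(2):
        wrapped = np.concatenate([vertices[-pad:, j], vertices[:, j], vertices[:pad, j]])
        out[:, j] = np.convolve(wrapped, kernel, mode="valid")
    return out


def random_walk_shape(cfg: RandomWalkConfig = RandomWalkConfig()) -> Outline:
    """Outline of the region swept by a thickened 2-D random walk.

    Deterministic in the seed.  If a seed happens to yield a degenerate or
    self-intersecting boundary, up to 10 derived reseeds are tried before
    raising :class:`ShapeGenerationError`.
    """
    for attempt in range(10):
        seed = cfg.seed if attempt == 0 else np.random.SeedSequence(
            [cfg.seed, attempt]
        ).generate_state(1)[0]
        rng = np.random.default_rng(seed)
        steps = rng.normal(0.0, cfg.step_sigma, size=(cfg.n_steps, 2))
        path = np.cumsum(steps, axis=0)
        region = LineString(path).buffer(cfg.path_width / 2.0, quad_segs=4)
        if region.geom_type == "MultiPolygon":
            region = max(region.geoms, key=lambda g: g.area)
        boundary = np.asarray(region.exterior.coords)[:-1]
        boundary = _smooth_closed(boundary, cfg.smoothing_window)
        try:
            outline = Outline(
                boundary, label=f"random_walk_{cfg.seed}", provenance="random_walk"
            )
            outline = resample_outline(outline, DEFAULT_RESOLUTION)
            outline = normalize_area(outline)
            if outline.to_shapely().is_valid:
                return outline
        except InvalidOutlineError:
            pass
    raise ShapeGenerationError(
        f"no simple outline after 10 reseeded retries (seed {cfg.seed})"
    )


def _regular_polygon(n: int) -> np.ndarray:
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([np.cos(th), np.sin(th)])


def _ellipse(aspect: float, n: int = 256) -> np.ndarray:
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([aspect * np.cos(th), np.sin(th)])


def _stadium(n: int = 256) -> np.ndarray:
    # rectangle of length 2 capped by two unit semicircles
    half = n // 2
    th1 = np.linspace(-np.pi / 2, np.pi / 2, half, endpoint=False)
    th2 = np.linspace(np.pi / 2, 3 * np.pi / 2, n - half, endpoint=False)
    right = np.column_stack([1.0 + np.cos(th1), np.sin(th1)])
    left = np.column_stack([-1.0 + np.cos(th2), np.sin(th2)])
    return np.vstack([right, left])


def ideal_forms(resolution: int = DEFAULT_RESOLUTION) -> list[Outline]:
    """The ten mirror-symmetric reference forms, each at 100 mm².

    Disc, regular polygons with 3/4/5/6/8 sides, ellipses of aspect ratio
    1.5/2/3, and a stadium.  Every form has at least one reflection axis
    (S = 1) and the convex ones have L = 0.
    """
    specs: list[tuple[str, np.ndarray]] = [
        ("disc", _regular_polygon(256)),
        ("triangle", _regular_polygon(3)),
        ("square", _regular_polygon(4)),
        ("pentagon", _regular_polygon(5)),
        ("hexagon", _regular_polygon(6)),
        ("octagon", _regular_polygon(8)),
        ("ellipse_1.5", _ellipse(1.5)),
        ("ellipse_2", _ellipse(2.0)),
        ("ellipse_3", _ellipse(3.0)),
        ("stadium", _stadium()),
    ]
    forms = []
    for label, verts in specs:
        outline = Outline(verts, label=label, provenance="ideal")
        outline = normalize_area(resample_outline(outline, resolution))
        forms.append(outline)
    return forms


def parametric_leaf(
    cfg: ParametricLeafConfig, resolution: int = DEFAULT_RESOLUTION
) -> Outline:
    """Generate one radial-harmonic leaf outline at 100 mm².

    The radius law is

        r(theta) = r_ell(theta) * (1 + d cos(k theta)
                                     + a (0.6 sin(2 theta) + 0.4 sin(3 theta)))

    with d = lobe_depth, k = lobe_count, a = asymmetry and r_ell the polar
    radius of an ellipse with the configured aspect ratio.  The modulation
    is clipped away from zero so the curve stays star-shaped (hence simple).
    """
    th = np.linspace(0, 2 * np.pi, resolution, endpoint=False)
    a_ax, b_ax = cfg.aspect_ratio, 1.0
    r_ell = (a_ax * b_ax) / np.sqrt((b_ax * np.cos(th)) ** 2 + (a_ax * np.sin(th)) ** 2)
    mod = (
        1.0
        + cfg.lobe_depth * np.cos(cfg.lobe_count * th)
        + cfg.asymmetry * (0.6 * np.sin(2 * th) + 0.4 * np.sin(3 * th))
    )
    if np.min(mod) <= 0.05:
        raise ShapeGenerationError(
            "lobe_depth/asymmetry combination pinches the radius to zero"
        )
    r = r_ell * mod
    verts = np.column_stack([r * np.cos(th), r * np.sin(th)])
    label = (
        f"leaf_k{cfg.lobe_count}_d{cfg.lobe_depth:g}"
        f"_a{cfg.asymmetry:g}_ar{cfg.aspect_ratio:g}"
    )
    outline = Outline(verts, label=label, provenance="parametric")
    return normalize_area(resample_outline(outline, resolution))


def parametric_sweep(seed: int = 0) -> list[Outline]:
    """A default grid of parametric leaves spanning both S regimes."""
    configs = [
        ParametricLeafConfig(lobe_count=5, lobe_depth=d, asymmetry=a, aspect_ratio=ar)
        for d in (0.0, 0.2, 0.3)
        for a in (0.0, 0.3, 0.6)
        for ar in (1.0, 2.0)
    ]
    shapes = []
    for i, cfg in enumerate(configs):
        out = parametric_leaf(replace(cfg, seed=seed + i))
        shapes.append(out.with_vertices(out.vertices, label=f"param_{i:02d}_" + out.label))
    return shapes
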