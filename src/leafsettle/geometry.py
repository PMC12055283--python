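"""Closed-polygon primitives for leaf-blade outlines.

Everything downstream (symmetry/lobedness metrics, digital mutations, shape
generators) operates on the :class:`Outline` type defined here: a simple,
counterclockwise closed polygon with vertices in millimetres.  Boolean
geometry (intersection, union, symmetric difference) is delegated to shapely;
this module owns validation, arc-length resampling, area normalization and
reflection.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import shapely.affinity
from shapely.geometry import Polygon

__all__ = [
    "Outline",
    "NormalizationConfig",
    "InvalidOutlineError",
    "GeometryError",
    "polygon_area",
    "polygon_perimeter",
    "polygon_centroid",
    "resample_outline",
    "normalize_area",
    "reflect_outline",
    "overlap_areas",
    "convex_hull_area",
]

logger = logging.getLogger(__name__)

Provenance = Literal["species", "mutated", "random_walk", "ideal", "parametric"]

#: Default vertex count used by the metric layer; balances boolean-op
#: robustness against discretization error (<0.1% on smooth shapes).
DEFAULT_RESOLUTION = 512

_DUPLICATE_TOL = 1e-9  # mm; consecutive vertices closer than this are merged


class InvalidOutlineError(ValueError):
    """The vertex list does not describe a valid simple closed polygon."""


class GeometryError(RuntimeError):
    """A boolean geometry operation failed on pathological input."""


def _dedupe_consecutive(vertices: np.ndarray) -> np.ndarray:
    """Drop repeated consecutive vertices (cyclically) within 1e-9 mm."""
    if len(vertices) < 2:
        return vertices
    nxt = np.roll(vertices, -1, axis=0)
    keep = np.linalg.norm(vertices - nxt, axis=1) > _DUPLICATE_TOL
    return vertices[keep]


def _signed_area(vertices: np.ndarray) -> float:
    """Shoelace signed area; positive for counterclockwise orientation."""
    x, y = vertices[:, 0], vertices[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    return 0.5 * float(np.sum(x * yn - xn * y))


@dataclass(frozen=True)
class Outline:
    """A simple closed polygon in millimetres.

    The polygon is closed implicitly (last vertex connects back to the
    first).  Construction validates and canonicalizes the input:

    * repeated consecutive vertices (within 1e-9 mm) are merged;
    * clockwise input is silently reversed to counterclockwise (logged),
      because mask-tracing tools emit either orientation;
    * self-intersecting input raises :class:`InvalidOutlineError` unless
      ``repair=True`` is passed, in which case a zero-distance buffer fix
      is attempted (silent repair can change area, so it is opt-in).

    Parameters
    ----------
    vertices
        ``(n, 2)`` array-like of (x, y) points in mm, ``n >= 3``.
    label
        Free-text identifier.
    provenance
        One of ``species | mutated | random_walk | ideal | parametric``.
    """

    vertices: np.ndarray
    label: str = ""
    provenance: Provenance = "species"
    repair: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        verts = np.asarray(self.vertices, dtype=float)
        if verts.ndim != 2 or verts.shape[1] != 2:
            raise InvalidOutlineError(
                f"vertices must be an (n, 2) array, got shape {verts.shape}"
            )
        if not np.all(np.isfinite(verts)):
            raise InvalidOutlineError("vertices contain non-finite values")
        # drop an explicit closing vertex if present
        if len(verts) > 1 and np.linalg.norm(verts[0] - verts[-1]) <= _DUPLICATE_TOL:
            verts = verts[:-1]
        verts = _dedupe_consecutive(verts)
        if len(verts) < 3:
            raise InvalidOutlineError(
                f"outline needs at least 3 distinct vertices, got {len(verts)}"
            )
        poly = Polygon(verts)
        if not poly.is_valid or poly.area == 0:
            if self.repair:
                fixed = poly.buffer(0)
                if fixed.geom_type == "MultiPolygon":
                    fixed = max(fixed.geoms, key=lambda g: g.area)
                if fixed.is_empty or fixed.geom_type != "Polygon" or fixed.area == 0:
                    raise InvalidOutlineError("zero-buffer repair failed")
                verts = np.asarray(fixed.exterior.coords)[:-1]
            else:
                raise InvalidOutlineError(
                    "outline is self-intersecting or degenerate; pass repair=True "
                    "to attempt a zero-distance buffer fix"
                )
        signed = _signed_area(verts)
        if abs(signed) <= 0.0:
            raise InvalidOutlineError("outline encloses zero area")
        if signed < 0:
            logger.debug("outline %r: clockwise input reversed to CCW", self.label)
            verts = verts[::-1]
        verts.setflags(write=False)
        object.__setattr__(self, "vertices", verts)

    # -- convenience ---------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def area(self) -> float:
        """Enclosed blade area A in mm²."""
        return polygon_area(self)

    @property
    def perimeter(self) -> float:
        return polygon_perimeter(self)

    @property
    def centroid(self) -> tuple[float, float]:
        return polygon_centroid(self)

    def to_shapely(self) -> Polygon:
        return Polygon(self.vertices)

    def with_vertices(self, vertices: np.ndarray, **kwargs) -> "Outline":
        """New outline with the same label/provenance but new vertices."""
        return replace(self, vertices=np.asarray(vertices, float), **kwargs)


@dataclass(frozen=True)
class NormalizationConfig:
    """Target blade area for scale normalization (default 100 mm²)."""

    target_area: float = 100.0

    def __post_init__(self) -> None:
        if not self.target_area > 0:
            raise ValueError(f"target_area must be > 0, got {self.target_area}")


def polygon_area(outline: Outline) -> float:
    """Enclosed area in mm² (shoelace magnitude; always positive)."""
    return abs(_signed_area(outline.vertices))


def polygon_perimeter(outline: Outline) -> float:
    """Closed-boundary length in mm."""
    v = outline.vertices
    return float(np.linalg.norm(np.roll(v, -1, axis=0) - v, axis=1).sum())


def polygon_centroid(outline: Outline) -> tuple[float, float]:
    """Area-weighted centroid of the enclosed region, in mm."""
    v = outline.vertices
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * cross.sum()
    if abs(a) < 1e-30:
        raise InvalidOutlineError("degenerate outline: zero area")
    cx = float(((x + xn) * cross).sum() / (6.0 * a))
    cy = float(((y + yn) * cross).sum() / (6.0 * a))
    return (cx, cy)


def _arc_lengths(vertices: np.ndarray) -> np.ndarray:
    """Cumulative arc length at each vertex plus the closing total."""
    seg = np.linalg.norm(np.roll(vertices, -1, axis=0) - vertices, axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def resample_outline(outline: Outline, n: int = DEFAULT_RESOLUTION) -> Outline:
    """Resample to ``n`` vertices equally spaced by arc length.

    Enclosed area is preserved within 0.5% for ``n >= 256`` on smooth
    shapes.  ``n`` below 16 is rejected.
    """
    if n < 16:
        raise ValueError(f"resampling resolution must be >= 16, got {n}")
    closed = np.vstack([outline.vertices, outline.vertices[:1]])
    s = _arc_lengths(outline.vertices)
    total = s[-1]
    target = np.linspace(0.0, total, n, endpoint=False)
    x = np.interp(target, s, closed[:, 0])
    y = np.interp(target, s, closed[:, 1])
    return outline.with_vertices(np.column_stack([x, y]))


def normalize_area(
    outline: Outline, cfg: NormalizationConfig | float = NormalizationConfig()
) -> Outline:
    """Uniformly scale about the centroid so the area hits the target.

    The study holds blade area constant (100 mm² by default) so shape is
    the only free variable; this is the single scale anchor used by every
    generator and the mutation operator.
    """
    if isinstance(cfg, (int, float)):
        cfg = NormalizationConfig(target_area=float(cfg))
    a = polygon_area(outline)
    factor = math.sqrt(cfg.target_area / a)
    cx, cy = polygon_centroid(outline)
    v = (outline.vertices - (cx, cy)) * factor + (cx, cy)
    return outline.with_vertices(v)


def reflect_outline(outline: Outline, axis_angle: float) -> Outline:
    """Mirror the outline about the axis through its centroid.

    ``axis_angle`` is measured in radians from the x-axis.  Reflection
    flips vertex order, which the Outline constructor repairs back to
    counterclockwise, so applying the operation twice returns the input.
    """
    cx, cy = polygon_centroid(outline)
    c2, s2 = math.cos(2.0 * axis_angle), math.sin(2.0 * axis_angle)
    rel = outline.vertices - (cx, cy)
    ref = np.column_stack(
        [c2 * rel[:, 0] + s2 * rel[:, 1], s2 * rel[:, 0] - c2 * rel[:, 1]]
    )
    return outline.with_vertices(ref + (cx, cy))


def overlap_areas(a: Outline, b: Outline) -> tuple[float, float]:
    """(intersection_area, union_area) of two outlines, in mm²."""
    pa, pb = a.to_shapely(), b.to_shapely()
    try:
        inter = pa.intersection(pb).area
    except Exception as exc:  # pragma: no cover - shapely GEOS failure
        raise GeometryError(f"boolean intersection failed: {exc}") from exc
    union = pa.area + pb.area - inter
    return (float(inter), float(union))


def convex_hull_area(outline: Outline) -> float:
    """Area of the convex hull, in mm² (>= the polygon's own area)."""
    return float(outline.to_shapely().convex_hull.area)
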