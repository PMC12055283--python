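"""Digital mutations: sinusoidal perturbation of leaf-boundary segments.

A digital mutation displaces the vertices of one or more boundary segments
along the local outward normal by a short-wavelength sinusoid, mimicking
the large-amplitude/short-wavelength margin perturbations of the
*asymmetric leaves1* phenotype.  The mutation magnitude is

    epsilon = delta_A / A0,

where A0 is the area of the original blade and delta_A the symmetric
difference between the original and the mutated blade, measured BEFORE the
mutant is rescaled back to the study's constant blade area.  Under constant
blade area a net signed-area change would be identically ~0, so the
symmetric difference is what actually quantifies "how much shape changed".

For small amplitude a on a boundary of perimeter P the symmetric-difference
area approaches the integral of |a sin|, giving the first-order law
epsilon -> (2/pi) a P / A0 (= 4 a R / A0 on a disc of radius R), used as an
independent check in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    Outline,
    normalize_area,
    polygon_area,
    polygon_perimeter,
)

__all__ = [
    "MutationSpec",
    "MutationResult",
    "MutationFailureError",
    "digital_mutate",
    "mutation_series",
]

#: Fraction of each segment's length over which the displacement is
#: cosine-tapered to zero at both ends, preventing C0 kinks.
_TAPER_FRACTION = 0.05


class MutationFailureError(RuntimeError):
    """The perturbed boundary self-intersects; reports the offending segment."""

    def __init__(self, segment_index: int, segment: tuple[float, float], amplitude: float):
        self.segment_index = segment_index
        self.segment = segment
        super().__init__(
            f"mutation amplitude {amplitude:g} mm creates a self-intersection "
            f"in segment {segment_index} spanning perimeter fractions "
            f"[{segment[0]:.3f}, {segment[1]:.3f})"
        )


@dataclass(frozen=True)
class MutationSpec:
    """Parameters of one sinusoidal boundary mutation.

    Attributes
    ----------
    amplitude : float
        Peak normal displacement in mm (>= 0).
    wavelength : float or None
        Sinusoid wavelength along arc length, mm.  None means
        perimeter / 24 ("short wavelength" relative to the blade).
    segments : tuple of (start, end)
        Non-overlapping perimeter fractions in [0, 1) marking the mutated
        stretches of boundary.  None draws one random quarter-perimeter
        segment using ``seed``.  ``(0, 1)`` mutates the full boundary, in
        which case the wavelength is snapped to an integer wavenumber so
        the sinusoid closes smoothly.
    phase : float
        Phase offset in radians.
    seed : int
        Seed for the randomized segment choice (only used when
        ``segments`` is None).
    """

    amplitude: float
    wavelength: float | None = None
    segments: tuple[tuple[float, float], ...] | None = ((0.0, 1.0),)
    phase: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude}")
        if self.wavelength is not None and not self.wavelength > 0:
            raise ValueError(f"wavelength must be > 0, got {self.wavelength}")
        if self.segments is not None:
            segs = tuple(tuple(map(float, s)) for s in self.segments)
            for f0, f1 in segs:
                if not (0.0 <= f0 < f1 <= 1.0):
                    raise ValueError(f"bad segment ({f0}, {f1})")
            for (a0, a1), (b0, b1) in zip(segs, segs[1:]):
                if b0 < a1:
                    raise ValueError("segments must be sorted and non-overlapping")
            object.__setattr__(self, "segments", segs)


@dataclass(frozen=True)
class MutationResult:
    """A mutated outline with its epsilon = delta_A / A0 bookkeeping."""

    mutated: Outline
    epsilon: float
    delta_area: float
    original_area: float
    amplitude: float = 0.0
    segments: tuple[tuple[float, float], ...] = field(default=())


def _outward_normals(vertices: np.ndarray) -> np.ndarray:
    """Unit outward normals at each vertex of a CCW polygon (central diff)."""
    tangent = np.roll(vertices, -1, axis=0) - np.roll(vertices, 1, axis=0)
    normals = np.column_stack([tangent[:, 1], -tangent[:, 0]])
    norms = np.linalg.norm(normals, axis=1, keepdims=True)
    return normals / np.where(norms > 0, norms, 1.0)


def _taper(s_local: np.ndarray, seg_len: float) -> np.ndarray:
    """Cosine ramp 0->1 over the first and last 5% of the segment."""
    ramp = _TAPER_FRACTION * seg_len
    w = np.ones_like(s_local)
    lo = s_local < ramp
    hi = s_local > seg_len - ramp
    w[lo] = 0.5 * (1.0 - np.cos(np.pi * s_local[lo] / ramp))
    w[hi] = 0.5 * (1.0 - np.cos(np.pi * (seg_len - s_local[hi]) / ramp))
    return w


def _resolve_segments(spec: MutationSpec) -> tuple[tuple[float, float], ...]:
    if spec.segments is not None:
        return spec.segments
    rng = np.random.default_rng(spec.seed)
    start = float(rng.uniform(0.0, 0.75))
    return ((start, start + 0.25),)


def digital_mutate(outline: Outline, spec: MutationSpec) -> MutationResult:
    """Apply one sinusoidal boundary mutation and quantify its magnitude.

    The outline should already be resampled to a uniform arc-length
    parameterization and normalized to the study blade area.  Vertices
    inside each requested segment are displaced along the local outward
    normal by ``amplitude * sin(2 pi s / wavelength + phase)`` where ``s``
    is the arc length from the segment start.  Displacements taper to zero
    over 5% of the segment length at each end (full-boundary mutations are
    not tapered; their wavelength is snapped to an integer wavenumber).

    delta_A is the symmetric-difference area between original and mutated
    blade before the mutant is rescaled back to the original blade area.

    Raises
    ------
    MutationFailureError
        If the displacement makes the boundary self-intersect; the first
        offending segment is named.
    """
    a0 = polygon_area(outline)
    perim = polygon_perimeter(outline)
    segments = _resolve_segments(spec)
    wavelength = spec.wavelength if spec.wavelength is not None else perim / 24.0
    if not wavelength < perim:
        raise ValueError(f"wavelength {wavelength:g} must be < perimeter {perim:g}")

    verts = outline.vertices.copy()
    seg_dist = np.linalg.norm(np.roll(verts, -1, axis=0) - verts, axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg_dist)])[:-1]  # arc length per vertex
    normals = _outward_normals(verts)

    mutated = verts.copy()
    for idx, (f0, f1) in enumerate(segments):
        s0, s1 = f0 * perim, f1 * perim
        seg_len = s1 - s0
        full_boundary = f1 - f0 >= 1.0 - 1e-12
        lam = wavelength
        if full_boundary:
            # closed sinusoid: integer number of wavelengths around the blade
            k = max(1, round(perim / lam))
            lam = perim / k
        mask = (s >= s0) & (s < s1)
        s_loc = s[mask] - s0
        disp = spec.amplitude * np.sin(2.0 * np.pi * s_loc / lam + spec.phase)
        if not full_boundary:
            disp = disp * _taper(s_loc, seg_len)
        mutated[mask] += disp[:, None] * normals[mask]
        try:
            trial = outline.with_vertices(mutated, provenance="mutated")
            if not trial.to_shapely().is_valid:
                raise ValueError("self-intersection")
        except Exception:
            raise MutationFailureError(idx, (f0, f1), spec.amplitude) from None

    mut = outline.with_vertices(mutated, provenance="mutated")
    delta = float(
        outline.to_shapely().symmetric_difference(mut.to_shapely()).area
    )
    mut = normalize_area(mut, a0)
    return MutationResult(
        mutated=mut,
        epsilon=delta / a0,
        delta_area=delta,
        original_area=a0,
        amplitude=spec.amplitude,
        segments=segments,
    )


def mutation_series(
    outline: Outline,
    amplitudes: list[float],
    spec_template: MutationSpec | None = None,
) -> list[MutationResult]:
    """Apply a progression of mutations of growing amplitude.

    ``amplitudes`` must be sorted ascending and start at 0 (the unmutated
    reference).  The resulting epsilon sequence is non-decreasing.  Any
    single failure aborts the series with the failing index reported.
    """
    amps = list(amplitudes)
    if not amps:
        raise ValueError("amplitudes must be non-empty")
    if amps[0] != 0:
        raise ValueError("amplitude series must start at 0")
    if any(b < a for a, b in zip(amps, amps[1:])):
        raise ValueError("amplitudes must be sorted ascending")
    template = spec_template if spec_template is not None else MutationSpec(amplitude=0.0)
    segments = _resolve_segments(template)  # fix the random choice across the series
    results = []
    for i, amp in enumerate(amps):
        spec = MutationSpec(
            amplitude=amp,
            wavelength=template.wavelength,
            segments=segments,
            phase=template.phase,
            seed=template.seed,
        )
        try:
            results.append(digital_mutate(outline, spec))
        except MutationFailureError as exc:
            raise MutationFailureError(exc.segment_index, exc.segment, amp) from RuntimeError(
                f"mutation series failed at index {i} (amplitude {amp:g})"
            )
    return results
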