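# Methods

This note documents the models, estimators and numerical choices behind
`leafsettle`, and what its synthetic experiments do and do not establish.

## Outline representation and canonicalization

All shapes are simple closed polygons with real-valued vertices in
millimetres. Construction canonicalizes input: consecutive duplicate
vertices (within 1e-9 mm) are merged; clockwise vertex order is silently
reversed to counterclockwise (mask-tracing tools emit either); and
self-intersecting input is rejected rather than repaired, because silent
repair changes area and would corrupt the mutation bookkeeping ε = ΔA/A₀.
An explicit `repair=True` opt-in applies a zero-distance buffer fix for
users who accept that risk.

Metric computations canonicalize further: outlines are resampled to 512
vertices equally spaced by arc length and rescaled about the centroid to
the study blade area of 100 mm². The constant area makes shape the only
free variable across the study; 512 vertices keep polygon boolean
operations robust while holding discretization error below 0.1% on smooth
shapes. Resampling uses linear interpolation along the cumulative
arc-length parameterization, so it is idempotent on already-uniform
outlines. Boolean geometry (intersection, union, symmetric difference,
convex hull) is delegated to shapely/GEOS.

## Symmetry number S

S(P) = max over axis angles θ ∈ [0, π) of IoU(P, reflect(P, θ)), with the
reflection axis through the area centroid. This attains 1 exactly when
the outline has at least one mirror axis and decays toward 0 with
increasing asymmetry. The search is a 180-angle coarse grid followed by
bounded scalar maximization (xatol 1e-4 rad) around the best grid point;
IoU(θ) is piecewise-smooth, and the test suite pins the optimized search
against a dense 3600-angle scan to 1e-3 on 50 random shapes. The axis is
constrained to pass through the centroid (no offset search): for the
near-balanced blades of interest the best mirror axis passes close to the
centroid, and the IoU objective degrades gracefully for small offsets.

## Lobedness number L

L = 1 − solidity = 1 − A/A_hull. It is zero exactly for convex blades,
grows monotonically with lobe depth in the parametric-leaf family at
fixed lobe count, and is invariant under similarity transforms. Radial
variance and boundary-roughness statistics were considered as
alternatives; hull deficit was chosen because it is parameter-free, has
the right fixed point (convex ⇒ 0), and matches the intuition of "mass
pushed out into lobes". Both S and L live behind a named-metric registry
(`SYMMETRY_METRICS`, `LOBEDNESS_METRICS`) so alternative definitions can
be swapped through the same `morphometrics()` call without API change.
Values are kept at full precision internally and rounded (2 decimals)
only for presentation.

## Digital mutations

Vertices inside each requested boundary segment are displaced along the
local outward normal (central-difference tangent, rotated) by
a·sin(2πs/λ + φ), with s the arc length from the segment start. The
displacement is cosine-tapered over 5% of the segment length at each end
to avoid C0 kinks and the self-intersections they seed; full-boundary
mutations are untapered, with λ snapped to an integer wavenumber so the
sinusoid closes. Default λ = perimeter/24, i.e. short relative to the
blade; it is exposed as a parameter. Displacement is bidirectional
(inward and outward along the sinusoid).

The magnitude ε = ΔA/A₀ uses the *symmetric-difference* area between
original and mutated outline, measured before the mutant is rescaled back
to the constant blade area. Under a constant-area protocol the net signed
area change is ~0 by construction and could not grow with mutation
strength; the symmetric difference is the quantity that does. Measuring
before the rescale isolates the mutation itself from the compensating
zoom. For small amplitude the law ε → (2/π)aP/A₀ (= 4aR/A₀ on a disc)
holds to first order and is verified within 10% in the tests. A mutation
that makes the boundary self-intersect raises an error naming the first
offending segment; the amplitude series helper enforces amplitudes
ascending from 0 and yields a non-decreasing ε sequence.

## Comparison shape sets

**Ideal forms** (10): disc, regular 3/4/5/6/8-gons, ellipses of aspect
1.5/2/3, and a stadium. All have a mirror axis (S = 1); the convex ones
have L = 0. The identity of a canonical "ideal" set is a choice; this one
spans aspect ratio and angularity while staying laser-cuttable, and is
overridable.

**Random-walk blobs**: a 2-D Gaussian random walk (2000 steps, per-axis
step sd 0.5 mm) is thickened to a 1 mm ribbon (shapely buffer); the outer
boundary of the swept region is smoothed with a 9-vertex circular moving
average (bounded curvature, hence cuttable), resampled and normalized.
Degenerate seeds are retried up to 10 times with derived seeds. The
resulting batch spans S ≈ 0.3–0.7 and L up to ~0.7 — comfortably covering
both settling regimes, wider than extant-leaf morphospace.

**Parametric leaves**: r(θ) = r_ellipse(θ)·(1 + d·cos(kθ) +
a·(0.6 sin 2θ + 0.4 sin 3θ)). The cosine term makes mirror-symmetric
lobes (depth d, count k); the two sine harmonics share no common mirror
axis (their axis sets π/4 + mπ/2 and π/6 + mπ/3 never intersect), so
a = 0 guarantees S = 1 and S decreases strictly as a grows. Parameter
combinations that pinch the radius below 5% of its base value are
rejected (the curve would stop being star-shaped).

## Terminal-speed estimation

Depth is positive downward; trajectories are analyzed in physical mm
(camera calibration upstream). Rolling ordinary-least-squares slopes are
computed over 1 s windows hopping by a quarter window; the steady window
is the earliest suffix, spanning at least two windows, within which all
window slopes agree with their median to 5% (a single trailing window is
never accepted — it trivially matches its own median and would admit
accelerating falls). The final speed is the Theil–Sen median-of-pairwise-
slopes estimate over the steady window, robust to tracking glitches. A
trajectory with no such suffix, or with a non-positive steady slope,
raises a non-terminal error. On the analytic transient
z = v(t − τ(1 − e^{−t/τ})) with τ = 0.5 s over 10 s the estimator
recovers v within 1%; on affine z it is exact regardless of lateral
flutter.

Trial aggregation reports mean, SEM = sd/√n and, given a control mean,
the relative speed; Re = v D/ν with defaults ν = 1e-6 m²/s (water) and
D = 0.01 m, placing the operating point at Re ≈ 100 per 1 cm/s of
settling speed. "Within 3% relative error" is interpreted as SEM/mean.

## Synthetic experiment

The lab experiment is replaced by a phenomenological model plus a
trajectory simulator; these exist to exercise the pipeline, not to model
fluid dynamics.

The (S, L) → relative-speed map is piecewise: for S > 0.75,
1 − 0.5·L clipped to [0.9, 1.1]; for S ≤ 0.75, a flat plateau at 0.775
(midpoint of the observed 15–30% slowdown), insensitive to L. The
constants are calibration values encoding the reported envelopes, not
fitted parameters. The hard threshold reflects the observed two-regime
structure; an optional logistic blend exists but defaults off, since
smoothing would add unsupported parameters. Whether the 15–30% spread is
shape-to-shape variation or measurement scatter is not resolvable from
the envelopes alone; the model treats it as a fixed plateau with trial
noise on top.

Simulated trials draw per-trial speeds Normal(mean, (0.15·mean)²) —
the 15% coefficient of variation is sized so that the 20–30-trial
protocol yields a ~3% relative SEM, matching the stated experimental
precision — and simulate z(t) with the exponential transient (τ = 0.5 s),
2 mm/1.5 Hz sinusoidal flutter in x, and 0.1 mm Gaussian position noise
at 50 Hz for 10 s. All randomness flows from one study seed through
`numpy.random.SeedSequence.spawn`: one child stream per shape, spawned
again per trial, so any subset is reproducible in isolation.

What passing the synthetic tests shows: the estimators recover known
inputs through realistic noise, the bookkeeping is exact, and the
pipeline preserves the regime structure it is fed. What it does not show:
anything about real leaf aerodynamics — there is no fluid model, no
tumbling/pitching dynamics, no dependence of flutter on shape, and the
regime structure is present by construction.

## Pipeline conventions

The control's relative speed is exactly 1 by construction. The regime
boundary is assigned by strict inequality: S > 0.75 is "high", S = 0.75
falls to "low" (the split is only approximate in nature, but a tie rule
must be fixed and documented). Shapes are re-normalized to the configured
blade area at ingest even if already normalized — one source of truth for
A. Shapes failing morphometrics or speed estimation are excluded, logged
and counted (rows out + excluded = shapes in). Study runs at a fixed seed
write byte-identical results CSVs (fixed column order, 6-significant-
digit floats, LF endings, '.' decimal).

Default problem sizes: the shared test study uses 30 random-walk shapes
(plus control, 10 ideal forms and an 18-leaf parametric grid) at 25
trials per shape; estimator calibration uses 200 simulated trajectories.
These sizes give stable statistics for the recovery checks while keeping
the suite quick to run.

## Known limitations

- The symmetry search maximizes over axis angle only, not axis offset.
- L = 1 − solidity saturates for deeply re-entrant shapes and does not
  distinguish lobe count from lobe depth.
- The steady-window detector assumes the terminal regime is reached and
  sustained; strongly oscillating descent speeds (tumbling) would need a
  cycle-averaged definition.
- Mask digitization resolution affects S for near-symmetric leaves;
  metrics are computed at a fixed 512-vertex resampling to stabilize
  this, but sub-pixel contour quality still matters.
- The synthetic settling model is phenomenological; no conclusions about
  real aerodynamics follow from it.
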