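# leafsettle

Tools for studying how the shape of a falling leaf blade controls how fast
it settles. Deciduous trees drop their leaves to recycle carbon and
nutrients close to the trunk, so — unlike seeds and pollen, which are built
to drift — leaves benefit from falling *fast*. `leafsettle` implements the
computational side of a sedimentation study of biomimetic paper leaves:
outline morphometrics, in-silico shape mutations, comparison-shape
generation, and trajectory-to-terminal-speed analysis, plus a synthetic
experiment so the whole pipeline runs and is testable without lab data.

It is aimed at researchers in plant biomechanics and low-Reynolds-number
sedimentation who work with 2-D blade outlines (from scanned leaf masks or
outline CSVs) and tracked settling trajectories.

## The quantities at the core

Every blade is a simple closed polygon, rescaled to a constant area
A = 100 mm² so shape is the only free variable.

- **Symmetry number** S ∈ (0, 1]: the maximal intersection-over-union
  between the outline and its mirror image, over all reflection axes
  through the area centroid. S = 1 for any shape with a mirror axis;
  S ≪ 1 for strongly asymmetric outlines.
- **Lobedness number** L ∈ [0, 1): one minus solidity,
  L = 1 − A/A_hull. L = 0 for convex (unlobed) blades and grows as the
  blade's mass is pushed into lobes.
- **Digital mutation**: a short-wavelength sinusoid added along the local
  outward normal of boundary segments, with magnitude
  ε = ΔA/A₀ — the symmetric-difference area between original and mutated
  blade over the original area. For a full-boundary sinusoid of amplitude
  a on a disc of radius R, ε ≈ 4aR/A₀ to first order.
- **Terminal settling speed** V_S: the steady slope of depth z(t), found
  by rolling-slope steady-window detection and a Theil–Sen fit, averaged
  over repeated trials (SEM = sd/√n). Speeds are reported relative to a
  circular disc control of equal area; the flow regime is characterized by
  the Reynolds number Re = v_s D/ν ≈ 100–300 (water, D ≈ 1 cm).
- **Regime threshold**: shapes with S > 0.75 settle like the disc (within
  ±10%, speed decreasing with L); shapes with S ≤ 0.75 settle 15–30%
  slower, insensitive to L.

## Worked example

Run a fully synthetic study — disc control, 10 ideal forms, an 18-shape
parametric-leaf grid and 8 random-walk blobs, 25 simulated settling trials
per shape — and analyse it:

```bash
leafsettle run --n-random 8 --trials 25 --seed 0 --out-dir demo
```

which prints:

```
Settling study results
======================================================
shapes in: 37   analysed: 37   excluded: 0
control: 'disc'  mean speed 10.091 mm/s
S range: [0.30, 1.00]   L range: [0.00, 0.61]
relative speed range: [0.736, 1.017]

relative speed by symmetry regime (threshold S = 0.75):
  high: n= 26  min=0.886  q25=0.926  med=0.963  q75=0.989  max=1.017
   low: n= 11  min=0.736  q25=0.752  med=0.772  q75=0.784  max=0.805
```

Reading the output: the 26 mirror-symmetric and near-symmetric shapes
(S > 0.75) settle within ~±10% of the disc control, while the 11
asymmetric blobs cluster 20–26% slower — the two-regime structure the
synthetic settling model encodes, recovered here from simulated noisy
trajectories by the full estimation pipeline. `demo/results.csv` holds the
per-shape table (S, L, V_S, SEM, relative speed, Re, regime):

```
shape_id,provenance,S,L,area_mm2,VS_mm_s,sem,relative_speed,reynolds,regime
disc,ideal,1,3.33067e-16,100,10.0909,0.271288,1,100.909,high
ideal_triangle,ideal,1,5.55112e-16,100,10.1828,0.238825,1.0091,101.828,high
...
```

The same steps are available as a library:

```python
from leafsettle import make_synthetic_study, run_study, morphometrics

study = make_synthetic_study(n_random=8, trials_per_shape=25, seed=0)
results = run_study(study.shapes, study.trajectories)
print(results.summary())
results.plot_shape_speed()           # S vs L coloured by relative speed
m = morphometrics(study.shapes[3])   # (S, L, area, perimeter, centroid)
```

Other subcommands: `leafsettle generate` (shape sets as outline CSV + SVG
contact sheet at laser-cuttable millimetre scale), `leafsettle mutate`
(digital-mutation series with the ε bookkeeping), `leafsettle track`
(trajectory CSV → settling summary), `leafsettle synth` (write a synthetic
study to disk).

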