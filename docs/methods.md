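# Methods

This note documents the models, algorithms and numerical choices behind
`cartiq`, and what its synthetic-data validation does and does not show
about real scanner data.

## Signal model and relaxometry

Spin-echo signal decays mono-exponentially with echo time,
`S(TE) = PD · exp(−TE/T2)`, where `PD` is the proton density (signal at
TE = 0, arbitrary units) and `T2` the transverse relaxation time (ms).
The default echo train is the seven-echo multi-echo spin-echo protocol
11.1–77.7 ms in 11.1 ms steps.  In practice the first echo of a MESE
train is contaminated by stimulated echoes; the package models this as a
multiplicative inflation `α ≥ 1` on echo 1 only, and the fitting stage
excludes the first echo by default.  With noiseless data the exclusion
removes the inflation bias exactly, which is what the artifact model is
for: it gives the exclusion rule a measurable consequence.

Voxel fits minimise the unweighted sum of squares by Levenberg–Marquardt
(`scipy.optimize.least_squares`, analytic Jacobian), started from the
ordinary least-squares regression of `ln S` on TE (`T2₀ = −1/slope`,
`PD₀ = exp(intercept)`).  The log-linear start is exact on noiseless
data, so the LM step is a no-op there; on noisy data it performs the
proper nonlinear refinement.  Numerical choices:

- **T2 bounds** [1, 500] ms.  The physiologic cartilage range is roughly
  10–100 ms; the wide band only guards against pathological fits.  LM
  runs unconstrained and a solution at or beyond a bound is flagged
  not-converged and invalid.
- **Validity rules.**  A voxel is invalid (NaN in the maps, excluded from
  all downstream means) if any included echo is ≤ 0, the mean included
  signal falls below a configurable floor (default 0), fewer than three
  echoes remain after exclusion, or the fit leaves the bounds.
- **Convergence** at relative RSS change < 1e-10 or 600 function
  evaluations (200 iterations × 3), whichever comes first.
- Chemical-shift-affected voxels are handled as an optional caller-
  supplied exclusion mask, not detected automatically.

## Phantom geometry

The phantom is deliberately minimal: a bone disc with a cartilage shell
over an arc of its circumference (an annular arc), surrounded by
background standing in for synovial space.  This preserves exactly the
two boundary types the laminar algorithm distinguishes — an articular
(background-facing) surface and a bone–cartilage interface — with a
curved geometry that exercises the distance transforms non-trivially.
Defaults: 0.365 mm in-plane pixels, 3 mm slices, an 18-pixel bone
radius, a 2.19 mm (6-pixel) shell, superficial/deep T2 of 52/39 ms and
PD 800.  A flat-slab layout is available where exact voxel-counting
symmetry is wanted; it spans the full grid width so its lateral edges
touch the volume boundary and are not mistaken for articular surface.

Noise is Rician — the magnitude of the true signal perturbed by
independent complex Gaussian noise of scale σ per channel — the correct
model for magnitude MRI.  At zero true signal the expected magnitude is
`σ·√(π/2)`, which the tests verify empirically.  At SNR above ~3 the
Gaussian approximation to Rician noise is adequate, and the default
noisy-phantom settings stay in that regime.  No scanner noise level was
available to copy, so σ is a free parameter; tests that need noise use
SNR ≈ 30 at TE = 0, a conservative value for 3 T cartilage imaging.

The phantom's laminar ground truth is produced by the same equidistance
rule the splitter implements (computed once per layout slice), so
closed-loop tests are exact; the splitter itself is independently
checked against a brute-force nearest-boundary scan.

## Laminar splitting and thickness

Boundary sets use 4-connectivity in-plane: a cartilage voxel is
articular if a 4-neighbour within its slice is background, bone-facing
if a 4-neighbour is bone; out-of-volume neighbours are neither.  A voxel
can be in both sets (single-voxel sheet).

Distances are 2-D Euclidean, per sagittal slice, centre-to-centre
between voxel centres, in mm.  Slice thickness (3 mm) is an order of
magnitude larger than the pixel (0.365 mm) and segmentation is
slice-wise, so 3-D distances would mix scales without adding accuracy.
A voxel is **superficial** iff `d_articular ≤ d_bone` — ties go to
superficial, a deterministic completion of the equidistant-border rule —
else **deep**.  The split is an exact partition of each region.

**Thickness** has no universally agreed voxel-level definition; the
package uses the local thickness `t(v) = d_articular + d_bone + s`
(`s` = pixel size), averaged over the region's voxels in the slice
range.  The `+s` term accounts for the half-pixel between each boundary
voxel centre and the true tissue edge.  This estimator is exact on slabs
(`k` voxel rows measure `k·s` for every `k ≥ 1`, including the
single-voxel sheet) and agrees with the analytic ring width of an
annulus within half a pixel; it needs no surface meshing and is
rotation- and translation-invariant on the pixel grid.

T2 means use 3 slices and thickness 7 slices, both centred on a
caller-supplied landmark central slice (odd counts enforced); the
landmark mirrors a manual anatomical choice and is never detected
automatically.  The morphometry acquisition's finer grid is emulated by
nearest-neighbour label resampling onto a grid with smaller pixels,
through the affines' world mapping, with voxel-edge alignment so integer
refinements map source voxels onto exact blocks.  Deformable anatomical
registration is out of scope; grids are related by their affines only.

## Statistics

For each response cell (region × layer; thickness uses layer "full")
the model is a linear mixed model with participant random intercepts,

    y = β₀ + β_g·group + β_t·time + β_gt·(group×time) (+ covariates) + b_i + ε,

fitted by REML via `statsmodels.MixedLM` on an explicit treatment-coded
design (reference group first, "healthy" promoted when present; time
reference "pre").  Covariates (age, BMI) are centred so adjusted cell
means refer to the sample covariate mean.  Reported quantities: adjusted
cell means per group×time, within-group changes (post − pre), and all
pairwise between-group differences of changes.  In the two-group case
the between-group difference equals the interaction coefficient
identically, and for balanced complete data the adjusted means equal the
raw cell means — both are asserted as invariants.

- **Intervals and p-values** use the normal (z) approximation, standard
  large-sample mixed-model practice; with 16 participants per group the
  CI coverage of the within-change sits near 0.94 (verified by
  simulation), slightly below nominal as expected for z intervals.
- **Šidák family**: the reported pairwise comparisons — G within-group
  changes plus C(G,2) between-group differences, m = 3 for two groups,
  m = 6 for the three-group sensitivity variant — configurable and
  recorded with every contrast row.
- **Degenerate inputs.**  Noiseless tables (residual variance
  numerically zero at the data's scale) are a supported closed-loop
  case: balanced GLS point estimates are exact regardless of the
  variance estimates, so estimates are returned with NaN SEs/CIs/
  p-values and a `degenerate` flag rather than an error.  Genuine
  non-convergence on non-degenerate data raises with the variance
  diagnostics.
- **Missing cells**: models fit on available rows (mixed models tolerate
  imbalance); a composite cell is NaN unless all of its regions are
  present, and NaN responses are dropped listwise per model.

The composite is the unweighted mean of the regional means per
participant × time × layer.  Note that the composite model's changes are
not the mean of the per-region model changes whenever voxel counts or
missingness differ by region — the two summaries answer different
questions.

## Cohort generator

`generate_cohort` inverts the model above: value = cell mean + centred
covariate terms + participant intercept `b_i ~ N(0, σ_b²)` + residual
`ε ~ N(0, σ_e²)`.  Defaults are a two-group design with 16 participants
per group, σ_b = 8 ms and σ_e = 2 ms — variance components of the order
implied by the reference tables' confidence intervals — with cell means
defaulting to published pre/post regional T2 values.  `balanced_table`
is the deterministic companion used for worked examples: symmetric
participant offsets and a ±residual pattern orthogonal to all design
effects, so every sample cell mean equals its target exactly while the
mixed model stays estimable.

All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); nothing touches global RNG state, and
sub-seeds are derived with `SeedSequence` so pipelines are reproducible
bit-for-bit.

## Problem sizes

Tests and the acceptance study run on deliberately small instances: the
standard phantom is a 9×64×64 (or smaller) stack with a few hundred
cartilage voxels per slice, pipelines image 2 participants per group,
and the parameter-recovery study uses 500 simulated cohorts of 32
participants.  These sizes give Monte-Carlo standard errors a few
hundredths of a millisecond wide for the recovery means while keeping
every suite fast on a single CPU.

## What passing tests do and do not show

The phantoms validate the *operators* — fitting, splitting, resampling,
thickness, modelling — against analytic truth and brute-force oracles.
They do not emulate k-space acquisition, coil sensitivities, B1
inhomogeneity, chemical shift, partial-volume averaging at oblique
boundaries, anatomic curvature, or segmentation error, so passing here
says nothing about those error sources in scanner data.  Likewise the
cohort generator matches the statistical model exactly by construction;
real cohorts can violate it (non-normal intercepts, heteroscedastic
layers), and the mixed model's robustness to that is not tested here.
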