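# Methods

This note records the models, conventions and numerical choices behind
`contourqa`, in the spirit of a statistical-software methods appendix.

## Data model and geometry conventions

A delineation is a stack of simple closed polygons, one or more per axial
slice, in patient-space millimetres (the native unit of DICOM RT-STRUCT).
On ingest every polygon is cleaned: consecutive duplicate vertices (within
1e-9 mm) and an explicit closing vertex are removed, orientation is
normalised counter-clockwise, and degenerate or self-intersecting input is
rejected rather than repaired. Shapes are never simplified — collinear
vertex runs are preserved so round trips are lossless.

Multiple polygons on a slice are treated as the union of their interiors;
holes are not modelled (pelvic target volumes are simply connected in
practice). Slices of two delineations are matched by z equality after
snapping to the common grid with a 0.01 mm tolerance, which is safe because
both contours derive from the same planning CT; slice positions must lie on
a common grid step (tolerance 1e-6 mm).

Areas and intersections are computed with exact polygon boolean operations
(shapely/GEOS), not by rasterisation, so raster resolution is not a hidden
parameter of the Dice coefficient. A raster grid (`GridSpec`) exists only
as an independent cross-check oracle in the test suite. The intersection
operands are ordered canonically (by WKB) before the boolean operation so
that `|A∩B|` is bit-for-bit symmetric in its arguments.

## Overlap metrics

**DSC** is volumetric per patient: numerator `2·Σ_slices |A_z ∩ B_z|·Δz`,
denominator `Σ|A_z|·Δz + Σ|B_z|·Δz`. A slice present in only one
delineation contributes to the denominator only, so missing cranio-caudal
extent lowers the score instead of being silently ignored. The median over
patients (MDSC) uses the midpoint convention for even cohorts; dispersion
is the sample SD (n−1). With a single patient the SD is reported as 0 with
an explicit `sd_defined=False` flag. The cohort median could in principle
also be taken over per-slice Dice values; the per-patient-then-median
construction is used because the cohort summary pairs one MDSC ± SD with a
patient count.

**Slicewise Hausdorff** is strictly 2D within a slice. Both boundaries are
resampled at arc-length steps of at most 0.1 mm (default; the induced error
is bounded by step/2 = 0.05 mm, far below the 1 mm decision threshold) and
the distance from a sampled point to the opposite contour is the exact
distance to its nearest boundary *segment*, so sparse vertices on the
opposite side do not inflate the result. For speed, a KD-tree on the
opposite side's sampled points first bounds the point-to-boundary distance
(`d_seg ∈ [d_pt − step/2, d_pt]`); only the points that can still attain
the maximum get the exact segment computation. This pruning is exact, not
approximate, and is verified in the tests against a dense brute-force
max–min oracle.

**MSHD** averages the slice distances over reference slices that have a
test counterpart. Unmatched reference slices are always counted and
reported; by default they are excluded from the mean (the distance is
simply undefined for an empty slice), with an optional `penalise` policy
that charges `slice_thickness × (slices to the nearest test slice)` for
users who prefer a penalty to silent exclusion. Zero matched slices is an
error, never a silent 0.

## Time analysis and decision rule

`TT = T1 + T2` per patient (first operation + independent check, minutes).
The cohort time saving is reported with two estimators that need not agree
on skewed timing data: the ratio of group means (default for the decision)
and the mean of per-patient savings. The paired Student t-test on TT uses
n−1 degrees of freedom, a two-sided p-value and a 95% CI of the mean
difference; zero-variance differences raise a degenerate-test error.

The acceptance rule is: at least 2 of {MDSC ≥ 0.75, MSHD ≤ 1 mm,
TT saving ≥ 50%} with the time-saving criterion mandatory. All comparisons
are inclusive — a cohort observed exactly at every threshold meets all
three criteria. The mandatory-criterion form is the stricter of the two
plausible readings of a "2 of 3" rule and matches the rationale that a
system saving no time has no reason to enter the workflow.

Outlier sensitivity removes the k patients with the worst combined rank
(rank by ascending DSC plus rank by descending MSHD, ties broken by
patient id) — a reproducible stand-in for the qualitative "irregular
anatomy" judgement made by eye in practice. The slice-thickness subgroup
comparison uses an unpaired, equal-variance Student t-test on the
independent-check time, because different patients are scanned at each
thickness.

## Atlas ranking

Profile similarity is a Gower-style mixed distance: numeric fields
contribute `|a−b| / cohort range`, clinical stage a scaled rank difference
on the ordinal ladder cT2 < cT3 < cT4, and categorical fields a 0/1
mismatch; the score is the weighted mean over fields present on both sides,
with weights renormalised over non-missing fields (the clinical template
tolerates partial entry). Weights default to uniform because no published
weighting exists; they are a configuration parameter. A numeric field that
is constant across the cohort carries no signal and contributes 0.
Ranking is ascending by distance with patient-id tie-breaks, hence fully
deterministic.

## Synthetic cohort generator

The generator emulates the *statistical structure* the analysis assumes,
not pelvic anatomy:

- **Shapes**: tapered tubes whose cross-sections are low-order Fourier
  perturbations of a circle, `r(θ,z) = R(z)·(1 + Σ_k a_k cos(kθ + φ_k))`,
  k ≥ 2, sampled at 180 vertices, with a smooth in-plane centre drift.
  Defaults (radius 28–40 mm, axial extent 100–130 mm, harmonics
  0.08/0.04/0.02) give CTV-like scale and mild irregularity.
- **Boundary disagreement**: each vertex is displaced radially (about the
  slice centroid) by a systematic bias plus a correlated Gaussian field —
  white noise low-pass filtered along the (periodic) boundary parameter and
  across slices, then rescaled so its spatial SD equals the requested σ.
  Smooth, spatially coherent disagreement is what inter-observer studies
  describe; vertex-wise jitter would be both unrealistic and invisible at
  Hausdorff scale. Correlation lengths are expressed as fractions of the
  circumference (`angular_corr`, default 0.2) and of the axial extent
  (`axial_corr`, default 0.5). Optional cranio-caudal truncation models
  extent disagreement; an optional localized Gaussian bump (default 12 mm
  amplitude, 50° width, half the axial extent) models grossly irregular
  anatomy such as a bulky uterine fibroma. A displacement that collapses a
  slice below a minimum radius (0.5 mm) raises an error rather than
  producing a degenerate polygon.
- **Cohort layout** (defaults): 44 patients — the first 14 atlas (sex split
  8 F / 6 M), the remaining 30 test; the first 29 at 5 mm slice thickness,
  the last 15 at 2.5 mm. Each test patient gets a reference, an
  expert-manual arm (bias 0.5 mm, σ 1.0 mm) and an automatic arm (bias
  1.0 mm, σ 2.0 mm, occasional one-slice truncation); two automatic-arm
  patients carry the bump outlier, their ids recorded in the provenance
  file together with the config hash and master seed.
- **Timing**: lognormal draws (times are positive and right-skewed, with
  SDs comparable to means in the automatic check column), moment-matched
  analytically to the target means/SDs — manual 13.12 ± 4.84 (T1) and
  10.20 ± 5.15 (T2) minutes, automatic 1.12 ± 0.44 and 9.72 ± 8.67. The
  independent-check mean is shifted by +2 min for 2.5 mm patients (thin
  stacks take longer to review; no published per-patient distributions
  exist, so both the lognormal family and the shift size are modelling
  choices).
- **Determinism**: every artifact is a pure function of (config, master
  seed); sub-seeds are derived with `numpy.random.SeedSequence.spawn`, and
  a null perturbation returns bit-identical vertices.

What passing tests on synthetic cohorts do *not* show: real CT anatomy has
organ-specific disagreement hot-spots, multi-polygon slices, and timing
correlated with anatomy complexity — none of which the generator models.
Synthetic results validate the *pipeline* (metrics, bookkeeping, decision
logic, power of the tests), not the clinical performance of any particular
auto-contouring product.

## Numerical choices and problem sizes

- Hausdorff resampling step 0.1 mm; brute-force test oracle at 0.02 mm with
  a 0.05 mm agreement band.
- Degenerate inputs raise typed errors (`DegenerateContourError`,
  `UndefinedMetricError`, `DegenerateTestError`, `GenerationError`) instead
  of propagating NaNs; an empty pair of delineations has no DSC, not DSC 0.
- Test cohorts are scaled-down versions of the default layout (10–24
  patients, 14–25 mm radii, 20–50 mm extents) with gentler end-slice taper
  so that the largest tested noise level (σ = 4 mm) stays clear of the
  collapse guard; replicate counts are 20 where distributional properties
  are asserted.
- The near-threshold regression cohort is tuned (bias 3.0 mm, σ 1.5 mm,
  automatic T2 target 9.26 min) so its MDSC sits just above 0.75 with a
  ~55% expected saving, pinning the decision engine's behaviour at the
  decision boundary.
- Reports serialise with sorted keys and default float repr, so a fixed
  seed yields byte-identical JSON across runs; nothing time- or
  path-dependent enters the report.

## Known limitations

- Hausdorff is within-slice only by construction; out-of-plane disagreement
  appears solely through unmatched-slice bookkeeping and the DSC
  denominator.
- Holes and multi-label structures are out of scope.
- The atlas step covers selection only; contour propagation is the
  commercial system's unpublished core and is not modelled.
- RT-STRUCT support is read-only and assumes axial, coplanar planar
  contours; slice thickness is inferred from z spacing (1.0 mm assumed for
  a single-slice set).
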