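# Methods

## Dose model and geometry

Dose distributions live on regular 3D grids (`GridGeometry`): origin and
spacing in mm, 0-based voxel indices, physical point = origin +
orientation·(index·spacing). Masks require axis-aligned geometries; oblique
grids are accepted only as resampling sources. A `frame_id` labels the
frame of reference; grids in different frames never compare equal, which
catches accidental cross-frame arithmetic early.

Spatial transforms follow the **pull-back convention**: they map a point in
the current planning frame to the corresponding point in the prior-course
frame. This direction is fixed by contract because resampling then needs no
transform inversion — each current voxel center is pushed through the
transform and the prior dose interpolated there. Transforms are inputs
(rigid 4×4 affines or displacement fields in mm); no registration is
computed here, matching the clinical reality that registration quality is
reviewed case-by-case by a human.

**Resampling** uses trilinear interpolation (`scipy.ndimage.map_coordinates`,
order 1): the standard choice for dose, bounded by the eight neighbouring
values and monotone. Points outside the prior grid's voxel-center bounding
box are assigned 0 Gy *and counted*; the tally is surfaced in provenance
because silent zero-fill can mask a misregistration or an inadequately
exported prior grid.

**Rasterization** of planar contours uses the voxel-center-in-polygon test
(matplotlib's path machinery) with nearest-slice assignment within half a
slice spacing; multiple polygons on a slice combine by XOR, so the even-odd
rule handles holes and islands. Rasterization is deterministic:
identical contours and geometry give bit-identical masks.

## Radiobiology

EQD2 of total dose D in n fractions with fractionation sensitivity α/β:

    EQD2 = D (D/n + α/β) / (2 + α/β)

The inverse is the closed-form non-negative quadratic root
`D = (n/2)(−α/β + sqrt((α/β)² + 4·EQD2·(2+α/β)/n))`; forward∘inverse is
identity to ~1e-15 relative across the clinical range (verified over
D ∈ [0, 100] Gy, n ∈ 1..40, α/β ∈ [1, 10] Gy).

Design choices that the underlying clinical procedure leaves open:

* **Per-voxel dose per fraction** is voxel dose / n — uniform fractionation
  across a course, the universal convention for EQD2 grids.
* **α/β on overlapping structures** is resolved by an explicit unique
  priority rank in the config (rank 1 wins); ties are rejected. Unlisted
  tissue gets a configurable default, shipped as 3 Gy (a generic
  late-responding-tissue value); institutional tables are deliberately
  external config, not package data.
* **DSF multiplies EQD2, after conversion** (course-wide or restricted to
  one structure, since recovery is organ-specific). DSF is a static
  multiplier in (0, 1]; no time-dependent recovery kinetics are modelled.
* **EQD2 only** — no BED or other equieffective models.
* The point-dose budget is floored at zero (never a negative allowance),
  and allowed doses are not rounded to deliverable increments.

EQD2 conversion of accumulated courses always uses the **current plan's
structures**; prior-course contours are never needed, which is what makes
the workflow practical across TPS vendors (prior contours don't require
curation). The conversion order is fixed: map physical dose → convert to
EQD2 on the current geometry → scale → sum.

## Feasibility screen

For each cumulative constraint the screen reads the prior metric value off
the summed EQD2 and flags:

* `INFEASIBLE` if prior ≥ limit (equality flagged infeasible — the safer
  reading of a saturated constraint);
* `ACHIEVABLE` if prior + full prescription ≤ limit — consistent with the
  structure-generation rule that P + R = A needs no gradient;
* `GRADIENT_REQUIRED` otherwise.

## Optimization structures

Given P (prior Dmax to the OAR within the target dilated by a configurable
near-margin, default 20 mm, computed by Euclidean distance transform on
voxel centers), prescription R and constraint A (all EQD2):

* P + R ≤ A → empty set; the equality case is treated as empty because the
  step d = ((P+R)−A)/N would be zero and all N shells degenerate.
* Otherwise thresholds D_i = P − i·d (clamped at 0; a zero threshold means
  "all remaining OAR voxels"), shells S_i = OAR ∩ {EQD2 ≥ D_i} minus the
  shells above, limits A − D_{i−1} with D_0 = P, physical limits via the
  inverse EQD2 conversion using the OAR's α/β (the limit protects the OAR).

Per-voxel conservativeness is a theorem of this construction, and is
asserted in tests: every voxel of S_i has actual prior EQD2 ≤ D_{i−1} =
assumed prior (for S_1 because P is the domain maximum), so planning to the
limits can never exceed A anywhere in the OAR. Shells are built OAR-cropped
by default; a flag builds whole-grid isodose shells for visual review. When
several OARs are processed, P is recomputed per OAR. Remaining OAR voxels
below the lowest threshold (`rest`) can be planned without regard to the
prior course.

## DVH and metrics

Cumulative DVHs use uniform bins (default 0.1 Gy) over equal-volume voxels.
D_xcc sorts voxel doses descending and accumulates whole voxel volumes —
no sub-voxel interpolation — returning the dose at which the running volume
first reaches x cc; structures smaller than x cc return their minimum dose
with a warning. This estimator is conservative and exactly reproducible,
and is tested against an independent full-sort oracle. Scorecard semantics:
PASS at achieved ≤ limit (exact equality passes; limits are "≤"
constraints).

## I/O

DICOM RT Dose is written as 32-bit unsigned integers with
`DoseGridScaling = max/(2³² − 1)`; round-trip error is at most half a
quantization step. Only the dominant dialect is read: axis-aligned
orientation, uniform frame offsets, dose units Gy — anything else is a hard
format error rather than a silent mis-scale. EQD2 grids carry
`DoseType = EFFECTIVE` / `DoseComment = EQD2` so the dose kind survives
round trips. Masks export to RT Structure Set via marching-squares contour
tracing at the 0.5 level per slice; mask → contours → mask round-trips
within one voxel surface layer. NIfTI (float32, bit-exact round trip)
serves as the TPS-neutral volume format inside case bundles; `case.json`
(versioned schema) ties courses, transforms, fractionation and scaling
together. The case log is append-only JSONL with timestamps — the
machine-readable analogue of a multidisciplinary planning record.

## Synthetic cases

The generator emulates the inputs of a multi-course reirradiation case:
each prior course is a flat high-dose core with a Gaussian shoulder,
`dose = peak·exp(−max(0, r − core_radius)²/(2σ²))`, which is smooth, has
spherical isodose surfaces, and makes shell generation analytically
checkable. Structures are spheres/cuboids rasterized on voxel centers.
Defaults — a 36×36×24 grid at 2 mm, a 60 Gy / 30-fraction prior course with
10 mm core and 8 mm shoulder, an 11 mm-radius OAR straddling the falloff
and a 6 mm-radius target abutting the core — are desk-scale stand-ins for a
typical focal reirradiation geometry. The worked-example preset sets the
prior peak to the inverse EQD2 conversion of 57 Gy at the course's
fractionation, so the OAR's near-target Dmax equals 57 EQD2 Gy exactly by
construction (the OAR intersects the flat core), not by fitting.

What the generator does **not** emulate: anatomical realism (no CT, no
heterogeneity), registration error (transforms are exact), multi-lobed or
non-convex dose distributions, and contouring variability. Passing tests
therefore demonstrate the correctness of the accumulation arithmetic and
the structure-generation algebra on smooth inputs, not robustness to
registration or segmentation noise in clinical data.

## Numerical choices and limitations

* Resampling out-of-extent threshold is the voxel-center bounding box;
  boundary samples use edge-value extension to avoid blending with the
  zero fill.
* Shell thresholds are compared with ≥ (voxels exactly at an isodose level
  join the hotter shell).
* Test and acceptance problem sizes (≈31 k voxels, 1000-case parameter
  sweeps) were chosen as representative desk-scale conditions; all
  quantities checked are resolution-independent algebra or converge at this
  scale.
* Oblique prior grids are supported as resampling sources only; oblique
  *target* geometries and non-uniform grids are out of scope, as are PACS
  networking, registration computation, and plan optimization itself — the
  structures and limits are inputs to an external TPS.
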