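# Methods

This note documents the models, conventions, and numerical choices behind
`ctvdelta`, in the order the pipeline runs.

## Coordinate and grid conventions

All geometry lives in a right-handed patient coordinate system in mm, with
axial slices orthogonal to z (the DICOM convention).  Voxel grids follow the
voxel-center convention: a voxel belongs to a structure iff its center lies
in the continuous set; the center of voxel (i, j, k) is
`origin + (i, j, k) · spacing`.  The default grid is 1×1×2 mm — the in-plane
resolution and slice thickness typical of a planning CT — deliberately
anisotropic so the distance-transform machinery is exercised in its realistic
regime.

## Mesh geometry

**Volume** is the signed-tetrahedron (divergence-theorem) sum
`|Σ v₁·(v₂×v₃)/6|`, exact for closed polyhedra; face windings are made
consistent (and the sign forced positive) before summation because exported
meshes have unreliable winding.  A surface with edges not shared by exactly
two faces is rejected with the open-edge count — volume is undefined there.

**3D Hausdorff distance.**  The directed sup is approximated by dense surface
sampling — by default 4 points/mm² (seeded, reproducible) plus *all* vertices
— but the distance from each sample to the opposing surface is the exact
point-to-triangle distance, not a vertex-to-vertex shortcut, which
systematically underestimates HD on coarse meshes.  The exact query uses a
kd-tree over triangle centroids: the k nearest-centroid triangles give an
upper bound, and every triangle whose centroid lies within (bound + largest
centroid-to-vertex radius) is then checked exactly, so the pruning is
provably lossless.  An exhaustive all-pairs scan with an independently
implemented scalar point-triangle routine confirms agreement to 1e-9 in the
test suite.

**2D axial Hausdorff distance** slices both meshes on a scanner-like grid of
planes at integer multiples of the slice spacing (default 2 mm), densifies
the resulting closed contours at ≤0.5 mm and measures exact point-to-segment
distances.  The per-structure summary is the maximum over slices where both
structures have contours — the most conservative reduction — and the full
per-slice map is always emitted so medians or other reductions can be
recomputed downstream.  Slices with a contour in only one structure are
counted separately as unmatched and excluded from the summary (2D HD is
undefined there).  Note one geometric consequence of the max reduction: for
nested smooth shapes the per-slice HD grows toward the inner structure's
poles (for concentric spheres of radii 10 and 15 mm it is
√(225−z²)−√(100−z²), largest at the most extreme shared slice), so the 2D
summary generally exceeds the equatorial gap.

Cohort summaries report median, sample SD, and min–max range for every
metric, because a bare "median (± x)" convention does not identify the
dispersion measure; emitting all three keeps the report unambiguous.

## Structure construction (GTV → CTV → CTV_Δ)

**Rasterization** sections the mesh at each voxel-center z and tests voxel
centers against the contour polygons with even-odd parity (holes supported);
centers strictly inside are occupied.  **Isosurfacing** (`mask_to_mesh`) is
marching cubes at the 0.5 level on a one-voxel zero padding, so structures
touching the grid edge still close.

**Margin expansion** computes the exact anisotropic-spacing-aware Euclidean
distance transform of the occupancy and occupies every center within
`margin + 0.25·mean(spacing)`.  The quarter-voxel term is a continuity
correction: the continuous boundary that a mask samples lies between the
outermost inside centers and their outside neighbors, so raw center-to-center
distances over-estimate the distance to the structure by about a quarter
voxel on average.  Without the correction an 8 mm expansion of a 10 mm ball
on a 1 mm grid lands 4% low against the analytic 4/3·π·18³; with it the error
stays within ~1.6% across the ball/margin/anisotropy combinations in the test
suite.  Dilating any sampled boundary estimate inherits the estimate's crest
noise, so a residual ±half-voxel-scale uncertainty is irreducible at a given
grid resolution.  Expansion is monotone in both the input set and the margin;
contraction is out of scope (negative margins are rejected).

**CTV construction** is `crop_to_barriers(expand(gtv, margin), barriers)`
with the composition order fixed — expand first, crop second — and the
barrier set holds three masks on the shared grid: air, bone, and a generic
anatomical boundary (body surface / fascia), kept separate so either reading
of "anatomical barrier" is expressible.  **CTV_Δ** is computed as a voxel
boolean (CTV_L AND NOT CTV_S), never as a mesh boolean, for robustness;
meshes are derived afterwards when Hausdorff analysis of CTVs is needed.
The default margin is 8 mm, the common GTV→CTV expansion in head-and-neck
protocols.

## Dosimetry

DVHs are cumulative ("volume receiving ≥ dose") over voxel-center dose
values at 0.01 Gy bins — fine enough that one-decimal percent reporting
(0.07 Gy at 70 Gy) is not bin-limited.  When dose and structure grids differ,
dose is resampled trilinearly at the structure's voxel centers; no Monte
Carlo sampling is involved anywhere, so every metric is deterministic.
D_x% reads the largest dose whose cumulative fraction is ≥ x%, linearly
interpolated between bin edges.  Prescription normalization (D95% = 70 Gy)
uses the exact empirical quantile of the target's voxel doses rather than the
binned curve, making normalization exactly idempotent and commuting with
uniform rescaling.  The hot spot outside a target accumulates whole voxels
from the hottest down until 0.03 cm³ is reached and reports the minimum dose
among them; no partial-voxel interpolation, so results are bit-stable.
OAR comparisons report absolute per-metric differences in percentage points
of the prescription, summarized by median/min/max across all OAR-metric
pairs.

## Acceptance criteria

Each coverage objective partitions the metric axis into three nested levels;
boundary values classify into the better level because the protocol's
inequalities are non-strict.  D95's "per protocol" level is the point value
100%, evaluated with a ±0.05-point tolerance to absorb rounding of
one-decimal inputs.  A plan is *accepted* iff no evaluated metric is an
unacceptable deviation — both per-protocol and variation-acceptable pass;
this is the only reading under which the packaged 14-case table yields its 13
accepted cases.  D2 (a near-maximum percentile) is classified with the same
bounds as D5.  The *under-coverage* flag is D98% < 95% — the per-protocol
level — which uniquely reproduces all flagged cells of the packaged table
(94.1 flagged, 95.6 not); metrics absent from the input (D5, hot spot when no
complement is supplied) are skipped and recorded as not evaluated.

## Synthetic phantom

The generator emulates the anatomy in which window-dependent delineation
differences arise, not a specific patient:

* **Geometry.**  A cylindrical "neck" (radius 45 mm) of soft tissue
  (HU 20–60) containing a cylindrical air cavity on the z-axis (radius 4 mm,
  HU −1000…−950), a bone cylinder (radius 7 mm at (0, −38), HU 800–1200),
  and air outside the body.  The S-window target is a C-shaped annular
  sector wrapping the cavity: inner radius 16 mm, outer 27 mm, angular
  extent 270°, z-extent 28 mm (volume ≈ 31 cm³, in the range of primary
  oropharynx/larynx GTVs).  The L-window target adds the *iceberg*: a radial
  extension toward the cavity over the central third of the angular extent.
  Its depth is solved in closed form from the configured S→L volume-increase
  fraction (default 9%, the median reported for window-based delineation
  differences): f = (φ_ice/φ)·d·(2r_in−d)/(r_out²−r_in²), giving d = 4.67 mm
  at the defaults.  The extension may not cross the cavity wall; requesting
  a deeper iceberg is an error.  The iceberg depth *is* the ground-truth
  Hausdorff distance between the S/L pair.
* **Barriers** are derived, not asserted: the air barrier is the lung-window
  HU range [−1000, 0] restricted to the body (which selects exactly the
  cavity), the anatomical barrier is the body exterior, the bone barrier the
  bone cylinder.
* **Dose.**  Plans are stood in for by an analytic conformal field — the
  prescription times a logistic function of the signed Euclidean distance to
  the target surface, `Rx·σ((s₀−s)/w)` with scale w = penumbra_sigma/2 and
  outward shift s₀ = 2.4·penumbra_sigma — then normalized to D95% = 70 Gy on
  the plan's own target.  The shift keeps the whole target on the flat
  shoulder (inside doses 95–107% of prescription for penumbra_sigma ≤ 3 mm)
  while voxels beyond 5·penumbra_sigma receive <5%.  The default
  penumbra_sigma = 3 mm gives an 80%→20% falloff width of ~4 mm, a plausible
  composite VMAT penumbra.  No optimizer is involved: the point is to
  exercise the DVH/criteria machinery deterministically, and plan
  optimization is explicitly out of scope.
* **Why the pattern follows by construction.**  Plan_S conforms to CTV_S, so
  CTV_Δ — at 2–6 mm radial depth beyond CTV_S, bounded by the cropped air
  cavity — sits in the penumbra: its D98% falls below 95% whenever the rim
  depth exceeds roughly one penumbra_sigma.  CTV_Δ is only a few percent of
  CTV_L's volume, so CTV_L's D95% stays near 100% and the plan is still
  accepted.  That is the qualitative pattern the cohort reproduces (most
  CTV_L accepted, the majority of CTV_Δ under-covered).
* **Cohort.**  `generate_cohort` draws inner radius U(16, 18) mm, ring width
  U(9, 11) mm, z-extent U(24, 32) mm, angular extent U(240°, 300°), volume
  increase U(0.05, 0.13) and penumbra_sigma U(2.5, 3.5) mm around the
  defaults; one global seed drives the draws, and each bundle's HU noise
  seed is a fixed offset of it, so cohorts are bit-reproducible.

What the phantom does *not* emulate: realistic CT texture and artifacts,
interobserver contour variability, free-form S/L differences (the difference
is a parametric radial extension, as the air-interface mechanism suggests),
optimizer-shaped dose with OAR trade-offs, and CTV-level volume differences
of the full 9% (barrier cropping absorbs part of the expanded iceberg, so the
phantom's CTV-level difference is ~3–4%).  Passing tests therefore validate
the analysis machinery and its closed-form behavior on known geometry — not
clinical effect sizes on real patients.

## Problem sizes and tolerances

The default test and acceptance runs use the 96×96×32 grid (≈0.3 M voxels),
meshes of 10–15 k faces from marching cubes, HD sampling at 2–4 points/mm²,
and a 14-phantom cohort; the whole suite runs in well under a minute of CPU.
Geometric assertions use the discretization-derived tolerances stated above
(0.5% for subdivision-4 icosphere volumes, 0.05 mm sampling tolerance for
analytic HDs, one voxel diagonal for parameter recovery, 3% for voxelized
volumes); the rules-engine worked example is exact.

## Known limitations

* The sampled Hausdorff sup is a lower bound that converges from below with
  sampling density; vertex inclusion makes it exact for polyhedra whose
  farthest points are vertices (all convex test shapes).
* RTSTRUCT reading is single-dialect: one CLOSED_PLANAR contour set per
  slice, no holes, nearest-slice z matching.
* The under-coverage rule (D98% < 95%) and the D2 classification bounds are
  protocol conventions configurable via the YAML objective set; the defaults
  encode the common head-and-neck protocol summarized above.
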