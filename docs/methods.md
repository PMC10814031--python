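# Methods

This note documents the model, the numerical choices, and the limits of what
the test suite demonstrates.

## Candidate enumeration

The planner treats every boundary voxel of the volume's bounding box as one
candidate insertion point and the segment from its center to the tumor
centroid as the candidate trajectory. Edge and corner voxels are assigned to
a single face by the fixed priority x−, x+, y−, y+, z−, z+, so the number of
candidates is exactly W·H·D − (W−2)(H−2)(D−2) (96 776 for a 128³ volume) and
each candidate corresponds to one cell of one face map. This direct
enumeration is equivalent to six perspective projections from the tumor
center with adaptively widened fields of view, taken to the point where the
projection grid and the bounding-box surface coincide cell for cell — and it
removes the projection machinery entirely.

The target is the unweighted centroid of the tumor voxels. Multiple tumors
are planned one at a time, by binding the `tumor` role to one label set per
run.

## Geometry on labeled voxels

All world geometry is in millimetres with 0-based voxel indices, a
voxel-center convention, and identity orientation (oblique CTs are rejected;
resample upstream).

**Surfaces.** Binary masks only carry surface information to about half a
voxel. Surface crossings (skin entry E, pleural entry P, H1/H4 collision)
are therefore evaluated on the trilinearly interpolated occupancy at level
0.5 — the same surface a marching-cubes mesh at iso 0.5 would triangulate —
with the mask pre-smoothed by a Gaussian of σ = 0.5 voxel. The half-voxel
smoothing suppresses the ±s/2 lattice waviness of the raw 0.5 level (which
otherwise biases grazing-ray collision tests outward, because any single
protruding surface bump triggers a hit), while the curvature erosion it
introduces, ≈ σ²·H for mean curvature H, is ~0.1 mm for the thinnest default
structures at 2 mm spacing — an order below the voxel size. Measured against
the analytic phantom oracle (below), this classifier outperforms both the
raw binary interpolation and nearest-voxel label tracing.

**Normals.** Surface normals come from the gradient of a Gaussian-smoothed
binary mask, with σ = 2 voxels by default. Voxelized surfaces develop flat
terraces of width ≈ √(2Rs) where they run perpendicular to a grid axis (R
the local curvature radius, s the spacing); on a 40 mm sphere at 2 mm
spacing, σ = 1 voxel leaves ~11° worst-case normal errors at those caps,
σ = 2 brings the worst case below 3°. Signed-distance-field gradients were
evaluated and rejected: the cone artifacts of distances-to-voxel-centers
make them substantially worse near the surface. The entry angle is
α = 90° − θ with θ the acute angle between path and normal, which makes α
independent of normal orientation; α is 90° for perpendicular insertion and
0° for a tangential path.

**Ray sampling.** Segments are sampled at uniform arc length, by default
half the smallest voxel spacing, which guarantees that any structure whose
intersection with the segment is at least one step long is sampled. Crossing
locations are refined by bisection to ≈ 0.015 mm; the residual error of E
and P is the surface-localization error itself, bounded by about half a
voxel (information-theoretic limit of binary labels on axis-aligned
surfaces). Distance fields are exact anisotropic Euclidean distance
transforms to obstacle voxel centers; per-ray minimum/maximum projections
use trilinear interpolation.

## Hard constraints

* **H1.** The segment I→C must not reach the 0.5 occupancy level of the risk
  union (default risk roles: bone, bronchi, vessels, heart, mediastinum,
  non-target lung). A candidate that never enters the target lobe at all is
  also classified as an H1-style failure.
* **H2.** E is the first in-body crossing from I; l = ‖E−C‖ must be
  *strictly* below the needle length (default 150 mm, a typical microwave
  antenna shaft; equality fails).
* **H3.** P is the first target-lobe crossing after E; α at P must be
  *strictly* above the threshold (default 20°; equality fails).
* **H4.** The expected ablation zone is the tumor dilated by the ablation
  margin (default 5 mm, the conservative end of the clinical 5–10 mm safety
  margin); dilated further by the required insertion depth (default 5 mm)
  and reduced by the lung parenchyma *and by the risk structures embedded in
  it* (vessels and bronchi are surrounded by parenchyma and already guarded
  by H1 — the depth constraint targets the pleural wall), the remainder is a
  forbidden shell the segment must not cross. For a tumor deep in the lung
  the shell is empty and H4 removes nothing.

Feasibility is the negation of the OR of the four failure layers, matching
the binary face-map convention (blocked = 0, open = 1).

## Soft constraints and selection

S1 evaluates the risk distance field only over the percutaneous portion
E→C: only the in-body path can injure structures (a configuration switch
restores full-ray semantics for comparison). S2's length is ‖E−C‖; the
package also implements the alternative formulation — a distance field grown
from the tumor centroid, clipped outside the body, maximum-projected along
the ray — as a cross-check, and the two agree to well under a voxel
diagonal. S3 assigns higher scores to larger entry angles, the direction the
clinical goal and the >70° excellence standard imply; the inverted variant
is available behind `s3_printed_form` for sensitivity analysis only.
Normalization extrema are taken over feasible cells only, so infeasible
outliers cannot compress the usable score range; a degenerate range (max =
min) scores 1.0 everywhere, i.e. all candidates satisfy that constraint
equally.

Dominance is weak inequality with at least one strict inequality; duplicate
objective vectors are all retained. The 2D fronts use a descending
sort-and-prune sweep, proven against an O(n²) dominance oracle in the tests.
The pairwise-front intersection can genuinely be empty (points non-dominated
in different projections); the fallback is the full 3D non-dominated set —
a superset of any pairwise intersection under strict dominance — computed by
an O(n log n) staircase sweep and flagged in the result. The aggregate is
the weighted sum G = λ₁R + λ₂L + λ₃A with weights renormalized to sum 1 on
load (a weighted-product form is available as an option). Ties in G break by
(R, L, A) descending and then cell id, so the ranking is invariant under
input permutation.

## Synthetic phantom and oracle

The phantom is built from analytic primitives: ellipsoids (torso, lungs,
heart, tumor), finite cylinders (trachea, main bronchi, intrapulmonary
vessels, mediastinal block), and elliptic torus arcs for the ribs. The rib
arcs follow the inner-skin cross-section scaled by a fit factor (0.93) and
the torso's z-taper, so the cage stays strictly between skin and lung — a
circular ring cannot do that inside an elliptical, tapering torso. Default
scene: 128³ voxels at 2 mm, body half-axes 105/95/125 mm, lungs 32/52/85 mm,
twelve ribs (7 mm thick) over six levels, three vessel branches per lung,
and a 15 mm tumor in the right lung with ≥ 5 mm clearance from every risk
structure. Jitter (±1 mm on rib levels and vessel endpoints, driven by the
seed) is applied mirror-symmetrically, so the phantom remains exactly
mirror-symmetric about the sagittal plane except for the tumor — the basis
of the mirror-symmetry tests. Identical spec and seed give bit-identical
volumes.

Because the primitives are analytic, trajectory occlusion has a
voxelization-independent ground truth: ellipsoid and cylinder hits are
closed-form quadratics; torus-arc hits are resolved by dense sampling
restricted to the slab |z − z_rib| ≤ tube radius (256 samples within the
slab, refined variants agree). On the rib phantom at 2 mm spacing the
voxelized H1 map agrees with this oracle on 99.2% of the 96 776 cells; on
the full phantom, whose thin vessel and bronchus silhouettes put more cells
within a voxel of a surface, agreement is 98.7%, with disagreements confined
to the silhouette bands.

What the phantom does *not* emulate: CT intensities (labels only),
interlobular fissures, respiratory or deformation effects, irregular tumor
shapes, and the fine vascular tree. Passing tests therefore demonstrate the
correctness of the geometry and optimization pipeline on segmentations of
realistic scale and topology, not segmentation robustness on clinical data.

## Verification

The verifier re-traces every returned path with the scalar geometry routines
(its own sampling, interpolation, and bisection code — none shared with the
planner's vectorized classification) and re-checks H1–H4 plus the three
excellence standards: distance to risk structures > 10 mm, length < 100 mm,
entry angle > 70°. A path is "excellent" when it meets all three (per-flag
counts are also reported). Scene identity is enforced by a checksum over
labels, grid, and role binding. On the default phantom all five returned
paths pass re-verification (pass rate 100%).

## Problem sizes and runtime

The shipped configurations are sized for a workstation run: the default
128³/2 mm phantom plans in roughly 12 s on one CPU (96 776 candidates,
≈ 250 samples per ray); the coarse 64³/4 mm variant used by many tests plans
in about 1.5 s; the spherical-lung calibration scenes run at 2 mm and
1.25 mm spacing. Clinical-resolution volumes (512×512×300 at 1.25 mm slices)
increase the candidate count about twelvefold and ray sample counts about
twofold; the per-cell engine is linear in both.

## Known limitations

* Straight, single-needle trajectories only; no tissue or needle
  deformation, no respiratory motion, no ablation temperature field.
* Entry localization and occlusion testing are bounded by voxel
  quantization; sub-voxel claims (e.g. ±0.5 mm skin-entry accuracy) hold at
  slice spacings ≤ 1.25 mm, and degrade proportionally on coarser grids.
* The pairwise Pareto intersection is empty on most realistic scenes, so
  the flagged 3D-front fallback is, in practice, the common path.
* Scores are normalized per scene; G values are comparable within one plan,
  not across patients.
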