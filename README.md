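# needlepath

Automatic planning of percutaneous needle trajectories for CT-guided thermal
ablation of lung tumors.

Thermal ablation destroys a lung tumor in situ by heating it through a
needle-shaped applicator inserted through the chest wall under CT guidance.
Choosing the insertion trajectory is a multi-objective problem: the needle
must not cross bones, airways, vessels, the heart, the mediastinum, or the
wrong lung; the percutaneous path must fit the applicator; the pleural entry
must be steep enough that the tip does not slip along the lung surface; and
among all safe trajectories clinicians prefer the ones farthest from critical
structures, shortest, and most perpendicular to the pleura. `needlepath`
automates this search over a labeled thorax segmentation, producing a ranked
shortlist for the clinician to review. It is aimed at researchers working on
preoperative planning pipelines; it is not a medical device.

## Method

Every boundary voxel of the CT bounding box is a candidate insertion point
*I*; the candidate trajectory is the segment from *I* to the tumor centroid
*C*. This enumeration is the fixed point of cube mapping with adaptive field
of view: exactly one sight line per bounding-box surface cell, with no camera
bookkeeping.

**Hard constraints** (violation excludes the candidate; the four binary
non-feasible maps are OR-combined):

* **H1** organ avoidance — the segment must not cross any risk structure.
  Occlusion is tested against the 0.5 level of the interpolated risk-label
  occupancy (a sub-voxel surface, the level-set analogue of a marching-cubes
  mesh collision).
* **H2** needle length — the percutaneous length *l* = ‖E − C‖ (E = skin
  entry) must be **strictly** less than the applicator length.
* **H3** entry angle — the angle α between the path and the lung surface at
  the pleural entry point P must be **strictly** greater than 20°.
* **H4** insertion depth — the expected ablation zone (tumor dilated by the
  safety margin), grown by the required depth, must not protrude through the
  pleura along the path.

**Soft constraints** become grayscale constraint maps over the feasible cells
and are min-max normalized there:

* S1: R = (d − d_min)/(d_max − d_min), where d is the minimum distance of the
  percutaneous path to the risk structures (3D Euclidean distance transform +
  per-ray minimum projection);
* S2: L = 1 − (l − l_min)/(l_max − l_min) — shorter is better;
* S3: A = (α − α_min)/(α_max − α_min) — steeper is better.

**Selection.** The three pairwise Pareto fronts of (R, L), (R, A), (L, A) are
computed by a sort-and-prune sweep and intersected; if the intersection is
empty, the full 3D non-dominated set is used (and flagged). The candidates
are ranked by the weighted sum G = λ₁R + λ₂L + λ₃A (λᵢ = 1/3 by default) and
the top k (default 5) are returned with full provenance, then re-verified
against H1–H4 by an independent tracer.

Because clinical CTs cannot ship with the package, a deterministic synthetic
thorax phantom (skin, torso, lungs, heart, mediastinum, bronchial tree,
vessels, rib cage, tumor) is built from analytic primitives, which also
yields an exact closed-form occlusion oracle for testing the voxel pipeline.

## Worked example

```bash
needlepath phantom --seed 1 --out out/phantom
needlepath plan --volume out/phantom/phantom.nii.gz \
                --roles out/phantom/roles.json --out out/plan
```

prints

```
phantom written to out/phantom (9 roles)
5 paths planned (feasible cells 57147/96776, pass rate 100.0%, excellent rate 100.0%)
  #1 face y- uv=(63,55) d=23.3mm l=76.2mm alpha=85.3deg G=0.863
  #2 face y- uv=(63,54) d=23.2mm l=76.3mm alpha=85.3deg G=0.863
  #3 face y- uv=(62,53) d=23.3mm l=77.2mm alpha=85.6deg G=0.863
  #4 face y- uv=(62,54) d=23.3mm l=77.5mm alpha=85.6deg G=0.862
  #5 face y- uv=(61,52) d=23.4mm l=78.1mm alpha=85.7deg G=0.862
```

Reading the output: of the 96 776 candidate insertion cells on the bounding
box, 57 147 satisfy all four hard constraints. The five returned paths enter
through the anterior chest wall (`face y-`), stay ≥ 23 mm away from every
risk structure (`d`), need ~76–78 mm of needle (`l`), and meet the pleura at
~85° (`alpha`); `G` is the aggregate score they are ranked by. The pass rate
is the fraction of returned paths that survive independent re-verification
of all four hard constraints; the excellent rate is the fraction satisfying
the stricter clinical standards d > 10 mm, l < 100 mm, α > 70°.

The plan directory also receives `plan.json` (machine-readable trajectories
with all raw values and scores), `report.json`/`report.csv` (the verifier's
per-path verdicts), 16-bit PNG face maps of feasibility and of the three
grayscale constraint maps, and `paths.vtk` (polylines for 3D viewers).
`needlepath verify` re-checks any saved plan against its volume.

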