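# Methods

`mitomorph` quantifies the morphology of mitochondrial networks from two
kinds of microscopy-style data: calibrated 2D fluorescence images of
TMRM-stained cells (confocal-style) and 3D label volumes with
anisotropic voxels (FIB-SEM-style). This note describes the models and
procedures, the parameters that matter, and the deliberate choices made
where several designs were defensible.

## Element model of a mitochondrial network

A binary mask is reduced to a one-point-wide skeleton
(`skimage.morphology.skeletonize`; 8-connected in 2D, 26-connected in
3D) and each connected component becomes a spatial graph with physical
(µm) coordinates. The component is decomposed into three element
classes:

* **end** — skeleton node of degree 1;
* **junction** — a merged clump of degree-≥3 skeleton nodes;
* **tubule** — a maximal junction-free path.

An unbranched organelle therefore has three elements (two ends, one
tubule); components with more than `cluster_element_threshold` elements
(default 7) are classified *clustered*, components with at least one
junction but at most the threshold are *branched*, the rest *isolated*.

Two cleanup steps precede counting, both configurable and both aimed at
rasterization artifacts rather than biology:

* **Junction merging.** Thinning produces clumps of adjacent degree-≥3
  pixels at a single biological branch point. All such pixels within a
  chessboard radius of 2 px are merged into one junction; without this,
  element counts — and hence the >7-element cluster rule — would depend
  on pixel-level accidents.
* **Spur pruning.** Terminal skeleton branches shorter than
  `prune_spur_um` (default 0.1 µm) hanging off a junction are removed;
  medial-axis whiskers at width perturbations are not branches. A
  component that is itself a bare short path is never pruned away.

On acyclic components the counts satisfy the Euler identity
`n_tubules = n_ends + Σ_j (deg_j − 2) − 1`, which the test suite asserts
on every synthetic fixture. Cycles are permitted (fused networks can
loop); a pure ring is reported as one closed tubule with no ends.

**Single-pixel components** are reported as isolated mitochondria with
(2 ends, 1 tubule, length 0): the smallest detectable object still
carries the minimal three-element structure. This is a classification
convention — the raw graph has one degree-0 node.

### Length measurement

Tubule length is the polyline length of the skeleton pixel chain after
an endpoint-preserving moving average (window ±2 points). Raw step sums
overestimate oblique digital lines by up to ~8 % (staircase bias);
averaging removes the zigzag while leaving collinear chains — axis
aligned or 45° diagonal — exactly at their step-sum value. With this
estimator, noise-free tubules of 1–7 µm at 0.1 µm/px are recovered
within max(2 px, 5 %) at every orientation on a 15° grid.

## Probabilistic length interpretation

A 2D projection does not reveal which tubules belong to the same
organelle. At a junction of degree *d*, the incident branch stubs may be
pairwise matched: a matched pair continues through the junction as one
mitochondrion, an unmatched stub is a terminus. Every combination of one
partial matching per junction is one *decomposition* of the cluster into
mitochondrial paths; for *d* stubs there are 1, 1, 2, 4, 10, 26, …
(involution numbers) partial matchings.

The whole-cell length distribution weights each decomposition of a
cluster equally (1/D for a cluster with D decompositions); within a
decomposition each constituent path contributes one count at that
weight, and accumulated counts over all clusters are normalized at the
end. Consequences worth knowing:

* a junction-free population reduces exactly to the empirical histogram
  of component lengths;
* a cluster's total mass is proportional to its expected path count, so
  fragmented readings of a large cluster carry more (smaller) paths;
* bins are uniform, default 0.25 µm over [0, 10] µm, extended upward if
  longer paths occur.

When the decomposition space of a cluster exceeds `max_enumeration`
(default 10,000), the space is sampled uniformly instead: one partial
matching per junction is drawn by the involution-number recurrence
(never materializing the matching list), the result is flagged
`sampled=True`, and the draw is seeded for reproducibility.

**Connectivity** is defined as `junctions / (junctions + ends)` pooled
over all components: 0 for a fully fragmented population, approaching 1
for a hyperfused one; a population with neither (pure rings) is defined
as 1. Other ratios exist in the literature; reported values should be
compared only within this convention.

## 2D pipeline

`binarize` thresholds a calibrated image (Otsu by default, fixed
threshold optionally) and removes 8-connected specks below
`min_object_area_um2` (default 0.04 µm², i.e. 4 px at 0.1 µm/px). Otsu
is known to fail when the foreground fraction is very small and the
photon budget low — the threshold falls inside the background mode and
the mask explodes. The synthetic renderer's defaults (below) sit in a
regime where this does not happen; with real data, inspect
`threshold_used` in the report.

Cell-level phenotype (short / intermediate / long / very long) is
assigned from the **median** of the cell's length distribution at
thresholds 1, 2 and 4 µm (configurable). The median of a binned
distribution is the midpoint of the first bin whose cumulative mass
reaches 0.5, ties resolved to the lower bin; the median rather than the
mean makes the label robust to one large cluster. These thresholds are a
reproducible stand-in for what is usually a manual call.

## 3D pipeline

Components are labeled with 26-connectivity. Skeletonization of
anisotropic volumes runs on a nearest-neighbour resampling to the
smallest axis spacing (thinning algorithms assume isotropy); lengths are
still reported in physical µm.

**Watershed splitting.** Fused clusters are split on the negated
Euclidean distance transform (computed with per-axis physical sampling).
Seeds are *h-maxima* of the transform: plain local maxima over-segment
elongated tubes, whose axial ridge is a plateau of near-equal maxima,
while suppressing maxima shallower than `h_um` (default 2× the smallest
voxel spacing, just above ridge voxelization noise) keeps one seed per
convex body and still separates bodies across a neck deeper than `h_um`.
Seed regions closer than `seed_min_distance_um` (default 0.15 µm, the
mitochondrial radius scale) are merged. Every foreground voxel is
assigned to exactly one sub-object; voxel conservation is asserted in
the tests.

**Volumes** are exact voxel counts × voxel volume. **Feret diameters**
use the convex hull of voxel centers in physical coordinates: feret_max
is the maximum pairwise hull-vertex distance; feret_min the minimum
extent over 256 quasi-uniform directions (Fibonacci sphere). Both are
corrected upward by one mean voxel diagonal because voxel-center hulls
underestimate surface extent; a single voxel reports exactly one voxel
diagonal.

**3D classification** reuses the 2D element rule and adds a
multi-instance criterion: a component is clustered if it has more than
the element threshold *or* watershed resolves it into ≥2 sub-objects.
Sub-objects inherit the parent component's phenotype.

## Condition comparison

Two conditions are compared by the 1D Earth-mover distance between
their pooled (mean per-cell) length distributions; on shared bins this
is `Σ |CDF₁ − CDF₂| · bin_width`, in µm. Commensurable uniform grids are
resampled onto the finer one; incommensurable supports are an error.
Significance comes from a cell-level permutation test — cells are the
experimental unit, so labels are shuffled between conditions and the
pooled EMD recomputed; the add-one estimator
`p = (1 + #{null ≥ observed}) / (1 + n_perm)` never reports p = 0 and is
deterministic under a fixed seed. Calibration (type-I error ≈ 5 %, power
≥ 0.9 for a +1 µm shift at 20 cells/arm) is verified by simulation in
the test suite.

## Synthetic data

The generators define the conditions under which the pipeline is
validated. 2D objects are capsules (all pixels within `radius_um` of a
centerline, distances in physical units) with lengths drawn from the
0.5–7 µm range observed in cumulus-cell confocal data, default
calibration 0.1 µm/px (the acquisition pixel size is not published; this
is a configurable assumption). Branched objects attach straight branches
to a trunk; element-count truth is computed analytically from the
construction topology, and constructions whose rasterization would merge
topology away from an attachment are rejected, so the recorded truth is
always correct. The fluorescence forward model is
`blur(mask + background) → Poisson(· × scale)/scale → + Gaussian(0, sd)`
with defaults PSF σ = 0.15 µm, scale = 100 counts/unit, sd = 0.02,
background = 0.05 — a photon budget at which Otsu segmentation of sparse
scenes is reliable (at ≈50 counts/unit it is not; see above).

3D objects are capsules on an anisotropic grid, default voxel size
(0.005, 0.005, 0.010) µm (x, y, z) matching FIB-SEM serial acquisition;
truth volume is the analytic capsule volume πr²L + 4/3·πr³
(hemispherical caps avoid skeleton artifacts at flat ends). Fused
fixtures chain near-spherical beads through thin necks; with `fuse=on`
touching objects share one label while the truth keeps individual
identities — the reference for watershed splitting.

What the generators do **not** emulate: out-of-focus haze and depth
attenuation, uneven illumination, organelle curvature, cristae,
neighbouring organelles, or segmentation errors of a learned model.
Passing tests therefore demonstrate correctness of the measurement
chain, not robustness to every real-world imaging artifact.

## Problem sizes and numerical choices

The test suite and the acceptance script use deliberately compact
problem sizes — 8–12 synthetic cells per 2D study, 200 tubules for
length-fraction recovery, 200–500 repeats for statistical calibration
with 199 permutations per test, 3D fixtures of ≤ 80×80×200 voxels at
0.01 µm — chosen so the full validation runs in minutes while keeping
every estimate's sampling error well inside the asserted tolerances.
Distribution masses are validated to sum to 1 within 1e-9; degenerate
hull inputs (collinear/coplanar voxel sets) fall back to raw points;
median ties go to the lower bin; the pixel graph treats each rasterized
point once, so all conservation checks are exact integer accounting.

## Known limitations

* The stub-matching decomposition model assigns decompositions, not
  organelles; its uniform weighting over decompositions is one defensible
  convention among several, and is recorded in every output's
  provenance block.
* Junction merging at radius 2 px can fuse genuinely distinct branch
  points closer than ~0.2 µm at the default calibration.
* Watershed splitting requires a neck at least `h_um` shallower than
  the adjoining bodies' radii; gradual tapers are not split.
* Feret diameters on very flat objects depend on the orientation
  sample density (256 directions ≈ 1 % extent error worst case).
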