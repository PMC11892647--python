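# Methods

## Coordinate and mesh conventions

All physical quantities are micrometres. Voxel index (i, j, k) maps to
the physical point ((i+0.5)·sx, (j+0.5)·sy, (k+0.5)·sz) — the
voxel-center convention — and this mapping is used identically by the
rasterizer, marching cubes, and every distance computation. Axis 0 is
the left–right (mirror) axis, axis 1 dorsoventral (+ = dorsal), axis 2
anteroposterior.

Meshes come from the topology-correct (Lewiner-style) marching-cubes
variant at iso-level 0.5 of a binary indicator, after padding the crop
by one background voxel so components touching the grid border still
close. Face winding is flipped to outward orientation. Enclosed volume
is the sum of signed tetrahedra against the mesh centroid (divergence
theorem); using the centroid rather than the origin keeps the
computation conditioned for meshes far from the origin, making volume
translation-invariant to ~1e-12 relative. A mesh is accepted for
volumetry only if every edge is shared by exactly two faces; the error
message reports the open-edge count. On a single voxel this variant
yields the half-voxel octahedron (volume 1/6 of a unit voxel) — a
useful fixed point for tests.

## The synthetic ganglion pair

The phantom is two ellipsoids (default semi-axes 115 × 125 × 145 µm)
separated by a 4 µm medial gap, populated with non-overlapping spheres:

* **Counts.** 542 left + 557 right somata; the internalized count is
  planted exactly per side by rounding `n_side × internal_fraction`
  (defaults give 526 of 1,099 internalized).
* **Volumes.** Lognormal with `logvol_mu = 7.6`, `logvol_sigma = 1.4`
  (log µm³), resampled above the 4 µm radius floor that encodes the
  "soma diameter > 8 µm" identification criterion. These values make
  the planted 99th:1st percentile volume ratio exceed 100 — the
  two-orders-of-magnitude heterogeneity — on every seed probed.
* **Superficial somata** are tangent to the ellipsoid from inside
  (depth 0) at area-uniform surface positions. Cells are excluded from
  three "nerve exit" regions where no cell bodies sit in real ganglia:
  two antipodal anteroposterior polar caps (half-angle 3°) and a medial
  cap (25°) where the commissure joins the pair — the latter also
  prevents somata from being buried when the closing ball bridges the
  inter-ganglion crevice. Face is assigned at generation time from the
  outward ellipsoid normal: dorsal / ventral by the sign of its
  dorsoventral component, "other" when the magnitude is below 0.3.
  Dorsal-face volumes are scaled by `dorsal_scale = 1.8`; this value is
  back-calculated from the reported rank-sum effect size between
  dorsal and ventral populations (AUC ≈ 0.63 at the default lognormal
  spread), since only the test statistic, not the effect magnitude, is
  reported for real ganglia.
* **Internalized somata** get a cell-to-surface depth uniform on
  [τ, 60] µm and log-volume `logvol_mu + depth_slope·depth + ε`,
  `depth_slope = −0.02`/µm. The noise SD of ε is solved by bisection of
  a Monte-Carlo estimate of Spearman(depth, volume) under the actual
  sampling scheme (including floor truncation) so the planted
  correlation hits `target_depth_rho = −0.368` on average. The depth
  ceiling of 60 µm keeps `depth + radius` below the ellipsoid's inward
  normal reach (min curvature radius ≈ 115²/145 ≈ 91 µm), so the
  recorded depth is the exact surface distance. Cells are placed along
  inward normals; placement uses rejection sampling, largest cells
  first, with strict pairwise non-overlap, and raises a descriptive
  error naming the failing cell if `max_place_attempts` is exhausted
  (over-dense configurations).
* **Bilaterality.** The right ganglion is sampled first; the left is
  sampled independently from the same distributions and mirrored across
  the midsagittal voxel boundary (grid sizes are even along axis 0, so
  mirrored voxel centers map onto voxel centers exactly). A
  `mirror_exact` flag instead copies the right side for tests that need
  identical distributions.
* **Rasterization** assigns label k to every voxel whose center lies in
  sphere k; non-overlap makes this unambiguous. The generating
  ellipsoid pair is stored as `true_mask` for recovery testing. All
  randomness flows from one `numpy.random.Generator` seeded by a single
  integer, so identical (config, seed) pairs give byte-identical label
  grids.

### What the phantom does and does not emulate

Real somata are irregular, deformable, and tile the ganglion cortex
almost completely; spheres cannot tile, so the phantom's superficial
layer has inter-cell gaps that real tissue lacks. Two consequences
matter when interpreting recovery results. First, the operational
surface (below) runs through chords bridging adjacent sphere tops and
therefore lies a few micrometres *inside* the generating ellipsoid on
average; internalized cells planted within that margin of τ are
measured as superficial. Across seeds the recovered internalized
fraction is 1–3 percentage points below planted, and depth-class
agreement is ~0.95–0.98 — the disagreement is confined to the τ
boundary, not spread over the population. Second, the phantom plants no
neurites, no grayscale noise, and no segmentation errors: passing
recovery tests demonstrates the geometry and statistics of the
pipeline, not robustness to annotation noise.

## The operational ganglion surface

The boundary "defined by the superficial cell bodies" is
operationalized as the morphological closing of the union of all cell
voxels with a Euclidean ball (default radius 32.5 µm), computed via
metric distance transforms so voxel anisotropy is respected, followed
by a fill of enclosed cavities. Holes are filled at the dilated stage —
where enclosure is most likely complete — so the subsequent erosion
only moves the outer boundary inward. If the result is not a single
26-connected component the largest is kept with a machine-parseable
warning.

The closing radius is the one genuinely free parameter of the surface
definition and was calibrated once against phantom ground truth: small
balls (≤ 15 µm) cannot bridge the gaps between spherical somata, so the
shell never closes and the interior cannot fill; very large balls
(≥ 40 µm) overshoot concavities and bias the internalized fraction the
other way while flattening the local normals used for face assignment.
At 32.5 µm the mask recovers the generating ellipsoids at Jaccard
≈ 0.89, the internalized fraction is recovered within the tolerances
above, and planted faces are recovered for ≥ 90% of superficial cells.
On real (non-spherical, tightly tiled) segmentations a smaller radius
would be appropriate; the parameter is exposed everywhere.

The surface mesh is smoothed with Taubin's non-shrinking two-pass
filter (λ = 0.5, µ = −0.53, 10 passes by default; vertex and face
counts preserved; 0 passes = identity). Taubin was chosen over plain
Laplacian smoothing precisely because net shrinkage would bias every
surface distance inward.

## Per-cell measurement

Per label: (1) processes thinner than 2.5 µm are removed by
morphological opening with a metric ball of half that diameter (below
voxel scale the opening is the identity), keeping the largest
26-connected component; a mask erased entirely by the opening is
reported as "all fine process" and the record excluded. (2) The soma is
meshed and its mesh and voxel volumes and centroid recorded. (3) The
minimum distance to the surface mesh is computed vertex-to-vertex with
a KD-tree (identical to exhaustive search; the default, matching a
nearest-neighbor search between mesh point sets) or, optionally, by
exact point-to-triangle distance (strictly tighter on coarse meshes;
implemented with a KD-tree candidate prefilter whose bound guarantees
exactness). (4) Depth class is strict: superficial iff d < τ, so a
cell at exactly τ is internalized. (5) Side is the sign of the signed
centroid distance to the midsagittal plane (default: the volume's
x-midplane). Face, for superficial cells only, is the dorsoventral
component of the outward surface normal, with |component| < 0.3 mapped
to "other"; internalized cells have face "none". Because a soma forms
its own bump on the operational surface, the normal is estimated by a
total-least-squares plane fit over a patch of surface vertices within
`distance + 7 × equivalent radius` of the centroid (single-vertex
normals reflect bump curvature and misassign ~15% of faces; the patch
fit brings planted-face agreement above 90%). (6) The soma-size filter
flags (never deletes) cells whose equivalent-sphere diameter from the
voxel volume is not strictly above 8 µm.

## Statistics

The battery always uses nonparametric tests; a Shapiro–Wilk p-value on
the volume distribution is reported as a descriptive flag only and
never gates anything.

**Mann–Whitney U.** U is computed from midranks; the reported statistic
is min(U₁, U₂) with U₁ + U₂ = n₁n₂. For untied pooled samples with
n₁ + n₂ ≤ 14 the p-value is exact: the proportion, over all
C(n₁+n₂, n₁) equally likely group labelings, of min-U values at least
as extreme as observed. Otherwise the normal approximation is used with
the tie-corrected variance and a 0.5 continuity correction. Its type-I
error at nominal 0.05, estimated under exchangeable nulls at n = 50 per
group over 2,000 replicates, lies within [0.03, 0.07].

**Spearman.** rs is the Pearson correlation of midranks (tie-safe),
snapped to ±1 when within 1e-12 (exact monotone data); the two-sided
p-value uses the t approximation with n − 2 degrees of freedom.
Constant input is an error (ranks degenerate).

**The battery** runs exactly four comparisons on included cells:
left vs right volumes, dorsal vs ventral volumes, superficial vs
internalized volumes, and Spearman of volume against surface distance
among internalized cells. No multiplicity adjustment is applied across
the four tests (they are reported individually, as is standard for this
kind of descriptive anatomy). A comparison with an empty group is
skipped with a logged warning. Raincloud-style output is provided as
plot-ready data (points, quartile box, kernel-density curve); rendering
is left to the caller.

## Problem sizes and determinism

The default grid is 312 × 180 × 204 voxels at 1.625 µm; the `reduced`
preset (204 × 116 × 132 at 2.5 µm) carries the identical planted
population and is the grid used by the multi-seed recovery study and
the acceptance script — one full pipeline run takes a few seconds
there, tens of seconds at full resolution. Every random draw in a run
descends from the single top-level seed; two runs with the same config
and seed produce byte-identical label volumes and identical reports up
to stage timings.

## Known limitations

* The spherical-soma simplification biases the operational surface
  slightly inward (quantified above); the package reports recovery
  metrics per run so the effect is visible rather than hidden.
* Depth-class agreement is bounded by cells planted near τ; with the
  default uniform depth distribution starting exactly at τ this is an
  intentional stress test, not an artifact to be tuned away.
* The exact Mann–Whitney path enumerates labelings and is limited to
  n₁ + n₂ ≤ 14 without ties; beyond that the corrected normal
  approximation is used (group sizes in the intended applications are
  in the hundreds).
* `min_surface_distance` in vertex-to-vertex mode inherits the vertex
  sampling of the meshes: it slightly overestimates true
  surface-to-surface distance on coarse meshes. The point-to-triangle
  mode removes the surface-side bias; both are exposed and reported.
* Face assignment ("dorsal"/"ventral"/"other") quantifies only the
  dorsoventral axis; anterior/posterior/lateral faces are not labeled.
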