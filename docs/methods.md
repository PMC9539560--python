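# Methods

This note documents the model, the numerical choices, and what the
synthetic tests do and do not demonstrate.

## From mesh to point cloud

The input is a triangulated surface mesh of a segmented root.  Vertices
are optionally filtered by a discrete curvature-change criterion: the
per-vertex measure is the angle deficit divided by one third of the
incident triangle area, and a vertex is kept when its measure deviates
from the global median by more than `curvature_threshold`.  The
literature this sampling idea comes from does not pin down the
estimator or threshold, so both are exposed as configuration; the
default threshold of 0 keeps every vertex.  If a positive threshold
keeps fewer than 1 000 points the module falls back to all vertices
rather than starving the pipeline.

Coordinates are multiplied by the scale factor (SF).  All geometric
constants downstream are fixed **in scaled units**:

| constant | value | meaning |
|---|---|---|
| patch diameter | 0.25 | cover-set ball diameter |
| min cylinder length | 3 × patch | shortest fitted cylinder |
| connection tolerance | 1 × patch | gap-filling trigger |

Fixing these in scaled units is what gives SF its meaning: the same
root scaled to more units of depth is modeled with relatively finer
patches and shorter cylinders.  The patch diameter is deliberately not
adaptive to the cloud extent — an adaptive patch would cancel the SF
effect and would let disconnected noise dilate the resolution.  With
the recommended working range (10–30 scaled units of root depth) a
scan gets 40–120 patch diameters along its depth.  Physical traits
are recovered by dividing lengths by SF, areas by SF², volumes by SF³;
input units are assumed centimetres throughout the trait sheets
(diameter classes of 0.1 mm are 0.01 cm).

## Cover sets and segmentation

The cloud is partitioned by a greedy seeded ball cover.  Points are
visited in an order derived from a seeded hash of their coordinates
(not their index), so adding unrelated points — segmentation speckle —
cannot perturb the cover over the root itself; this makes speckle
removal exactly neutral for the reconstructed model rather than only
approximately so.  Patches are neighbors when any member points come
within one patch diameter.

The base is the topmost patch of the largest connected component
(z up, depth increasing downward; the root collar sits at the soil
surface).  Restricting to the largest component means isolated
vertices or noise floating above the collar can never anchor the
model.  Components not connected to the base are discarded — this is
the mechanism by which soil-segmentation speckle is removed.

Region growing is organized by geodesic level sets: each patch gets
its BFS hop distance from the base; hops are grouped into bands of 2
(single-hop annuli are too ragged on an irregular patch graph to form
connected rings); each band is split into connected components; and
components on consecutive bands are linked by patch adjacency.
Walking this component tree yields the segments:

- a single successor continues the current segment;
- at a bifurcation, the successor whose direction best continues the
  segment's recent growth direction (cosine ≥ 0.75 against the
  centroid track of the previous few layers) continues it, and the
  other successors seed children one ramification order deeper;
- if no successor passes the alignment test (a symmetric fork), the
  segment ends and every limb becomes a child.

Direction persistence was chosen over raw component size after the
size proxy proved unreliable on tapering roots, where the main axis
near its tip becomes thinner than a young lateral.  Two repair passes
keep the tree honest: a child spawned at its parent's final layers
whose direction continues the parent is spliced back (this undoes
transient ring fragmentation, where the walk's chosen fragment dies
and a sibling captures the remaining limb), and childless segments
shorter than 3 layers are folded back into the parent layer they
branched from (these are surface artifacts, not branches).
Ramification orders are recomputed from the final tree (taproot = 0).

## Cylinder fitting

Within a segment, layers are grouped into disjoint runs spanning at
least the minimum cylinder length, and one circular cylinder is fitted
per run.  The fit minimizes Σ(dᵢ − r)² where dᵢ is the point-to-axis
distance, over four parameters (two in-plane offsets of the axis
point, two tilt components), with the radius eliminated analytically.
`scipy.optimize.least_squares` drives the iteration with parameter
bounds that exclude the classical degeneracy in which a thin arc is
explained by a huge cylinder far away; a fit whose axis leaves the
point set's spread is rejected outright.

Junction contamination — points of an attached branch inside a run —
is handled twice: a pre-filter drops points whose distance to the
run's centroid chord is an outlier (beyond 2.5 NMAD), and the fit
itself can iterate up to three trim-and-refit rounds on its radial
residuals.  The reported radius is the **median** point-to-axis
distance, insensitive to residual contamination; on noiseless
cylinders it equals the mean exactly.  The radius is clamped to
[0.5, 2] × the run's median chord distance.  Cylinder length is the
extent of the (inlier) projections on the fitted axis; consecutive
cylinders of a segment are trimmed where their extents overlap so
material is not double-counted.  Segments too short for any run get a
single fallback cylinder between their endpoint centroids with radius
equal to the median point-to-chord distance.

Gap filling inserts cylinders where the model is disconnected: within
a segment, between a cylinder's end and its successor's start
(skipped when they interpenetrate); across a branch attachment, only
the void between the **parent cylinder's surface** and the child's
first cylinder is bridged, with the mean of the flanking radii.
Bridging from the parent axis instead of its surface would count the
parent's interior twice.

## Traits

- Volume Σπr²l, length Σl, lateral surface area Σ2πrl, rooting depth
  from base to deepest cylinder end; all converted by the SF rules.
- "Area" is the lateral (side) cylinder surface, consistent with the
  magnitude relationships in published whole-root tables.
- The percent ratios 100·V/A, 100·V/L, 100·A/L are computed on
  unrounded totals and reported to two decimals; they satisfy
  (%V/A)·(%A/L)/100 = (%V/L) exactly.
- Root-ball metrics come from cylinder endpoints (not the raw cloud,
  so noise removal propagates): planar convex hull and alpha-shape
  area of the horizontal projection, 3D hull and alpha-shape volume.
  Alpha shapes are circumradius-filtered Delaunay triangulations /
  tetrahedralizations (default alpha radius: a quarter of the
  bounding-box diagonal), which are subsets of the Delaunay complex
  and hence never exceed the convex hull.  `ball_diam_avg` is defined
  here as the mean over the 10 depth layers of the maximal horizontal
  pairwise extent (empty layers count 0); `ball_diam_max` is the
  global maximum.  These two conventions are local definitions —
  published tables print the quantities without defining them.
- The spread matrix is exactly 10 depth layers × 18 azimuth sectors of
  20°, sectors starting at +x counter-clockwise seen from above; the
  cell value is the maximum horizontal distance from the vertical axis
  through the base.  Cells are populated by points sampled densely
  *along* each cylinder axis rather than by the two endpoints alone;
  with endpoints only, the max-statistic jumps between adjacent cells
  under small fitting perturbations, which poisons temporal
  differencing.
- Distribution sheets use half-open classes [k·w, (k+1)·w) with
  w = 0.1 mm (diameter), 1 cm (depth), 10° (zenith from the upward
  vertical, 0–180°), 10° (azimuth, 0–360°); main = order 0,
  lateral = order ≥ 1; per-class totals conserve the group totals to
  float precision.  The lateral sheet's fourth classifier is read as
  the zenith distribution, completing the
  diameter/depth/azimuth/zenith quartet.

## Temporal registration and growth

Coarse alignment is closed-form orthogonal Procrustes (SVD with
reflection guard) on hand-picked point pairs.  Refinement is trimmed
ICP: each iteration matches every source point to its nearest target
point, keeps the best `overlap_fraction` of pairs (0.35–0.40 is
typical for a younger scan against a grown one), and solves the rigid
step on the kept pairs; iteration stops when the kept-pair rms stops
improving.  Statistical outliers (mean 8-NN distance beyond 2.5 σ) are
removed first; no features or derivatives are used.  In rotation-only
mode the step is constrained to a rotation about the matched centroid;
the transform object stores this as rotation + center with exactly
zero translation.  Full six-degrees-of-freedom ICP can trade rotation
against translation when the overlap is partial, so the rotation-only
mode is both the physically appropriate and the numerically accurate
choice when the pot never leaves its holder — on synthetic two-week
series it recovers an applied 3° rotation to better than 0.1°, where
the free variant can err by more than 0.5°.  A registration whose
final rms exceeds a quarter of the target extent is flagged as failed.

Growth is the difference of spread matrices with both scans binned on
the later scan's base and depth grid.  Deltas can be slightly negative
(a few millimetres) where the fitted cylinder chains of the two weeks
disagree at cell boundaries; this jitter is bounded by the fit
residual scale and does not indicate shrinkage.  Large negative deltas
do indicate registration or fitting error and trigger a warning.

## Robust statistics and the SF sweep

NMAD = 1.4826 × MAD, the Gaussian-consistent scale estimate; on 10⁵
draws from N(0, σ=2) it recovers σ within 2%.  Summaries report mean,
SD, median and NMAD plus 95%-trimmed variants (symmetric 2.5%
quantile trimming — the trimmed-sample reading of a "95% CI" column).
The median model over an odd number of stochastic reconstructions
(default 5 runs) is always a realized model, never an average; for
even counts the lower-middle model is taken.

The SF sweep reconstructs the same mesh at several SFs, extracts the
median model's traits per SF, and summarizes each trait across SFs
with an NMAD/|median| robustness ratio.  On the default synthetic
root, a five-value sweep spanning coarse-to-fine working resolutions
(SF 0.35–1.1, i.e. 7–22 scaled units of depth — deliberately
straddling the recommended window at the coarse end, where thin-root
detection degrades) shows the expected pattern: rooting depth is
SF-stable (relative NMAD below 5%, typically below 1%), while total
length and ramification count vary most, because coarse resolutions
miss thin laterals entirely.

## The synthetic generator and the limits of what the tests show

`synthetic_root` emulates a potted taprooted plant scanned weekly: a
tapering vertical taproot (default 20 cm, radius 0.4 → 0.15 cm),
straight laterals with configurable attachment depth, azimuth, zenith,
length and radius (defaults: six laterals, 3–6 cm long, radii
0.12–0.2 cm, zenith 100–130°), optional axis waviness, Gaussian
surface noise, and disconnected speckle blobs placed inside the pot
but clear of the root.  Tube meshes are sampled at uniform surface
density (0.1 cm axial ring spacing, ring vertex count proportional to
circumference), matching real CT surface meshes, whose vertex density
does not depend on root thickness.  Ground truth is computed from the
skeleton in closed form (frustum volume and lateral area per edge), so
it is exact.  Growth series strictly add material (elongation plus
optional new laterals) and can carry a recorded rigid perturbation.

What passing tests show: the geometry pipeline is correct on clean,
well-resolved tubular geometry down to a few percent in volume and
length, branch counting is exact when branches are several patch
diameters long and thick relative to the patch size, registration
recovers known rigid motions, and the accounting identities
(conservation, ratio algebra, unit rules) hold exactly.

What they do not show: performance on real CT artifacts — touching or
fused roots, partial surfaces, non-circular cross sections,
root-hair-scale structure below patch resolution, segmentation errors
that connect soil to root (connected noise is *not* removed; only
disconnected components are), or heavily tortuous architectures.  On
real thin roots the relative error grows, as the fit residual is fixed
by the data while the signal shrinks with the radius.

## Problem sizes

Default test geometries use meshes of roughly 6 000 vertices
(0.1 cm resolution on a 20 cm root system), reconstructions of 30–60
cylinders, Monte-Carlo fits over 100 seeds, and a 5 SF × 5 run sweep;
the full test suite and the acceptance script each complete in well
under a minute on one CPU.  These sizes were chosen so a desk-scale
run exercises every code path at full fidelity; the pipeline scales to
million-face scans linearly in points via the kd-tree cover.
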