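# Methods

This note records the models, conventions and numerical choices behind
`epitopo`, in the order the pipeline runs them. Coordinates are (row, col),
0-based, origin top-left, half-open pixel extents, everywhere.

## Synthetic epithelium generator

The generator stands in for segmented micrographs of confluent monolayers. It
rasterizes the Voronoi tessellation of `n_cells` seed points (nearest-seed
assignment of every pixel), carves 1-px background boundaries between regions,
enforces 4-connectivity of every cell, and marks as region of interest (ROI)
the cells whose Voronoi domain does not touch the image frame.

Tunable parameters:

- `n_cells` (default 515) and `image_size` (default 512×512 px) set the cell
  density; 515 cells at 512 px gives ≈ 500 px²/cell, a typical apical-surface
  scale for segmented wing-disc images and the mean cells-per-image of the
  regime the generator emulates.
- `lloyd_iterations` (default 3): rounds of centroidal (Lloyd) relaxation of
  the seeds. 0 gives a Poisson–Voronoi mosaic with a broad polygon
  distribution (~28% hexagons); each round narrows it. The default was
  calibrated once against the stereotyped distribution of proliferating
  epithelia (≈ 3% tetragons, 28% pentagons, 46% hexagons, 20% heptagons):
  three rounds give ≈ 46% hexagons (measured 1.8 / 22 / 46 / 25 at 515 cells).
  The generator is pentagon/heptagon-symmetric, whereas real tissue is
  pentagon-skewed; tests therefore pin the hexagon fraction, not the tails.
- `polygon_shift` ∈ [−1, 1] (default 0): 0 keeps the relaxed-random baseline;
  positive values interpolate the seeds toward a strongly relaxed (30 extra
  Lloyd rounds) configuration, moving mass from pentagons/heptagons into
  hexagons — the direction of developmental progression toward hexagonal
  packing; negative values add Gaussian seed jitter (σ = 0.25 · |shift| ·
  mean spacing), broadening the distribution. The two-condition default shift
  of 0.15 was chosen once from the measured dose–response: it moves the
  hexagon fraction by ≈ 2–3 percentage points, which at the canonical
  15-vs-16-image design yields a small but significant MANOVA difference
  (p ≈ 0.004–0.03 in calibration runs) — the effect scale the method is meant
  to detect.

What the generator does **not** emulate: membrane intensity signal (images are
born segmented), cell division and rearrangement dynamics, mechanical
anisotropy, pentagon-skewed tails, and segmentation errors. Passing tests on
synthetic mosaics therefore validate the measurement and statistics machinery,
not any segmentation step, and say nothing about robustness to segmentation
artifacts in real micrographs.

Determinism: a (spec, seed) pair is bit-reproducible; multi-image sets spawn
per-image seeds from one `SeedSequence`.

## Cell geometry

Standard regionprops conventions: axis lengths are those of the ellipse with
the region's normalized second central moments; `relation_axis` =
major / minor; `convex_hull_ratio` is solidity (pixel area / convex-hull
area), 1 for convex smooth-sided cells. All cells are measured — cells outside
the ROI supply neighbour values. "Relation neighbours" ratios are
f(cell) / mean(f over contact-graph neighbours); the orientation (cell over
neighbour mean) is fixed so that homogeneous tissue gives ratios of 1.

Degenerate regions (zero minor axis, i.e. 1-px-wide lines) are rejected as
segmentation faults rather than silently patched.

## Contact network

Adjacency uses a single-disc rule: cells i, j are linked iff dilating region i
by a disc of radius r overlaps region j — equivalently the inter-region gap is
≤ r px. The default r = 4 follows the field convention for segmented membranes
a few pixels wide; for the generator's 1-px membranes r = 2 already captures
every true contact, and the tests that compare the contact graph with the
Delaunay triangulation of the generator seeds account for rasterization:
short Voronoi edges (corridors narrower than a pixel or two) are lost or
bridged, so ~80–90% of in-ROI cells carry exactly the Delaunay neighbour set
and per-class polygon counts deviate by a few percent. The deviation shrinks
as raster resolution grows, confirming a discretization effect.

Edge weights count the background (membrane) pixels reachable from both
regions; they feed **only** the node strength (weighted degree). Clustering,
eccentricity, betweenness and all whole-image path metrics are computed on the
unweighted graph; betweenness is normalized by (n−1)(n−2)/2.

Per-node metrics are evaluated on the full graph (out-of-ROI cells still
provide connectivity); the twelve whole-image metrics on the subgraph induced
by in-ROI nodes. A disconnected in-ROI subgraph falls back to its largest
component with a logged warning (mosaics of confluent tissue are connected in
practice). Two degenerate conventions keep the 40-vector finite: on regular
graphs the degree–degree Pearson correlation and assortativity (0/0) are
reported as 0. The community partition behind the modularity entry uses greedy
modularity maximization after canonicalizing node order by centroid, making
the value invariant to cell relabeling (the greedy merge otherwise breaks ties
by label).

The 40 image characteristics are: means and sample standard deviations
(ddof = 1) over in-ROI cells of the per-cell quantities (entries 1–28, with
single-average entries for the major and minor axes), then the twelve global
network metrics (29–40). The 14-entry per-cell vector used by the correlation
assay is the geometric block plus the five relation ratios plus the four node
metrics; the number of sides is deliberately excluded.

## Correlation assay

Cell similarity is the Pearson correlation across the 14 min–max-normalized
features with population-style σ (division by 14). Self-correlation is exactly
1 and every value is ≤ 1; negative values are possible in principle but never
survive the high thresholds (≈ 0.99) at which the network is informative, so
no clipping is applied. Edges use Corr ≥ threshold (boundary ties are
measure-zero). `threshold_sweep` bisects on the largest-component size, which
is non-increasing in the threshold; component-size jumps inside the target
range raise an explicit error with the attainable range. The same-sided
linkage statistic is the fraction of edges joining equal polygon classes, with
an add-one-corrected permutation p from shuffling class labels over nodes.

## Polygon statistics

Per-image polygon-class frequencies are computed over in-ROI cells; classes
outside 3–10 (segmentation oddities) are excluded with a warning. The
two-group comparison is a one-way MANOVA on the frequency vectors of classes
4–8 — classes 3, 9, 10 are discarded because they are absent in some images
and their zero-inflated columns degrade the within-group covariance; dropping
them also removes the sum-to-one collinearity. Wilks' Λ with Rao's F
approximation is reported (for two groups all four classical statistics
coincide); frequencies enter untransformed (no arcsine), which the type-I
calibration test shows is adequate at these sample sizes. Exactly coincident
group means short-circuit to (Λ = 1, F = 0, p = 1). Each group needs ≥ 6
images for the 5-variate test; smaller groups are rejected (or skipped with a
warning inside the high-level model).

## Separation descriptor and feature selection

Candidate feature subsets are min–max normalized per column (constant columns
map to 0 with a warning; the transform is idempotent), centered, and projected
on the two leading eigenvectors of the covariance matrix; each component's
sign is fixed so its largest-magnitude loading is positive. The separation of
the two groups in the score plane is

    descriptor = trace(B) / trace(W),

with B = Σₖ Nₖ (cₖ − c)(cₖ − c)ᵀ and W = Σₖ Σᵢ (xᵢₖ − cₖ)(xᵢₖ − cₖ)ᵀ on the
2-D scores. B + W equals the total scatter. Unlike the classic
Calinski–Harabasz index no (N − k)/(k − 1) factor is applied; the unscaled
trace ratio is the variant whose magnitude (order 0.1–2 at N ≈ 31) matches the
intended operating range. The descriptor is invariant to rigid motions of the
scores and non-decreasing in a planted between-group mean shift (both tested).

The beam search scores all C(p, 2) feature pairs and keeps the best 10; each
kept pair is extended by every unused feature keeping the best 5 (50 trios);
then the best 2 per trio (100 quartets); from the quintet stage on, one
extension per candidate, and a branch whose descriptor no longer improves
stops. The search halts at subsets of 7; the reported subset is the argmax
over everything scored (so a better earlier subset is never discarded). Ties
in candidate ranking break lexicographically by feature index, making the
search fully deterministic. Rank-deficient submatrices (which cannot support a
2-D projection) score −∞ and drop out. On 8-feature tables the beam matches
exhaustive enumeration of all subsets of size ≤ 7 in ≥ 90% of random
instances (tested); it remains a heuristic on 40 features.

## Randomization null

Each loop reassigns the images to two mixed groups preserving the original
sizes — with groups of nA and nB images, mixA takes ⌈nA/2⌉ of A and ⌊nB/2⌋ of
B (for the canonical 15 + 16 design: 8 + 8 versus 7 + 8) — then re-runs the
full beam search for the descriptor and, when per-image polygon distributions
are available, the MANOVA for its p. The real-label values are located in the
two null series; the independence report pairs (p, descriptor) per loop with
the p = 0.05 marker and counts of loops beating the real labels on each axis.
Draws are without replacement from a seeded generator; a fixed seed reproduces
the series exactly.

## Problem sizes

Defaults keep every stage tractable on one CPU: the acceptance run uses the
canonical study design (15 + 16 images, 515 cells each at 512×512 px), a
400-loop randomization null — a scaled-down stand-in for a 4000-loop run,
sufficient to place the real labels above the 99th percentile — and a
1500-cell subsample for the O(n²) correlation assay; it completes in roughly
seven minutes. The test suite uses smaller mosaics (70–500 cells), 500-replicate
distribution-level calibrations, and 50-seed recovery simulations, and runs in
about two minutes. The MANOVA type-I calibration simulates polygon
distributions directly (Dirichlet–multinomial at the observed regime) rather
than rendering 15 500 mosaics per replicate; the per-image rendering path is
covered separately by the end-to-end pipeline tests.

## Known limitations

- Rasterization bounds the fidelity of the contact graph to the ideal Voronoi
  adjacency (see above); conclusions about very short cell contacts are
  resolution-limited.
- The descriptor handles exactly two groups; no multi-class variant and no
  cross-validation of the selection is provided.
- The beam search optimizes in-sample separation; with 40 features and ~31
  images a selected subset always separates the groups somewhat, which is
  precisely why the randomization null is part of the method rather than an
  afterthought.
- Correlation networks on tens of thousands of cells are O(n²); the pipeline
  caps the assay at a seeded subsample.
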