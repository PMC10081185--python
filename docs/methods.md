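# Methods

This note documents the models implemented in `vasckit`, the conventions
and parameter defaults, what the synthetic data generator does and does not
emulate, and the numerical choices made where the design was open.

## Spatial-graph model

A vessel network is an undirected graph of **nodes** (branch points or
terminal ends) and **segments** (vessels between two nodes).  Each segment
carries an ordered polyline of centreline **points** with a local radius in
μm; the interval between consecutive points is a **sub-segment**.  All
coordinates are world μm; a voxel `(k, j, i)` of an isotropic raster with
origin `o` and voxel size `v` has world position `o + v·(i, j, k)` (arrays
are indexed `(z, y, x)`, 0-based).

Direction (parent → child) is never stored.  Every analysis derives it from
a root node at run time; the default root heuristic picks the degree-1 node
whose incident segment has the largest mean radius (the cut feeding-artery
stub), with ties broken to the lowest node id.  Segment endpoints must
coincide with their node positions within a tolerance (10⁻⁶ μm after
ingestion; configurable for foreign files that store rounded coordinates).

The AmiraMesh SpatialGraph ASCII reader interprets the `thickness` point
attribute as a **radius** by default, with a flag to halve it where a file
stores diameters; the choice should be confirmed against magnitudes the
source documents (e.g. a human kidney artery radius is ~3 mm).

## Ordering

* **Strahler order** (centripetal): terminal segments are order 1.  At a
  junction whose children have orders {o₁…o_k}, the parent receives
  max+1 when at least two children attain the max, else the max.  This is
  the standard generalization of the binary rule to k > 2 children.
* **Topological generation** (centrifugal): the root-adjacent segment is
  generation 1; crossing a node with ≥ 2 children increments the label.
* Degree-2 passthrough nodes affect neither scheme (the generation counter
  increments at branching nodes only), so subdividing a segment changes no
  labels.
* Cycles reachable from the root are an error, not silently broken: the
  analyses assume an arterial *tree*, and a cycle indicates a segmentation
  or skeletonization defect that should be repaired, not masked.

## Morphometry conventions

* length = Σ ‖pᵢ₊₁ − pᵢ‖; radius = mean of sub-segment radii, where a
  sub-segment's radius is the mean of its two endpoint radii; volume =
  Σ π r² l over sub-segment cylinders.
* **Tortuosity = path length / chord length (≥ 1).**  Sources sometimes
  state the inverse (chord/path); reported per-order values ≥ 1 in the
  field's tables are only consistent with path/chord, so that is the
  default and a `literal_tortuosity` flag provides the inverse.
* **Length:radius ratio** is length / radius.  A "length:diameter" label
  is common in the literature, but published per-order values match
  length/radius (e.g. mean length 2600 μm at mean radius 45 μm printed as
  57.4); a diameter-based variant is a one-line division by 2.
* Branching angles use chord vectors pointing away from the junction
  (tortuosity ignored); a straight continuation scores 180°, and
  child–child angles are reported for every unordered pair at junctions
  with more than two children.
* The midpoint inter-vessel distance excludes only the segment itself from
  its nearest-neighbour search; an option additionally excludes segments
  sharing a node, since adjacent midpoints trivially dominate in dense
  trees.
* The segment midpoint is the point at half the cumulative path length,
  linearly interpolated within a sub-segment.

## Scaling statistics

* **Branching ratio.**  Counts per order follow `N = N₀ γ^(−O)`.  γ is
  defined as `exp(−slope)` of the ordinary least-squares fit of ln N on O
  over orders with N ≥ 1 — the reading of the count law that reproduces
  published ratios from published count tables (the printed kidney counts
  give γ = 2.925 against a printed 2.921).
* **Murray's law.**  At each junction with ≥ 2 children,
  `x = (Σ Rᵢ³)^{1/3}` (all children summed) and `y = R_parent`, using mean
  segment radii.  The default regression is on (x, y); a `cube_space` flag
  regresses the cubes instead.  Radii can be rescaled (e.g. μm → m with
  `unit_scale = 1e-6`) so intercepts are comparable with analyses done in
  metres; the slope is scale-invariant.  The theoretical law is the
  identity line in either space.
* **Outlier removal** approximates the ROUT procedure of common
  statistical software (whose exact internals are proprietary): a
  least-absolute-deviations line (IRLS), residual scale from the 68.27th
  percentile of |residuals| (the robust SD), per-point t statistics on
  n − 2 df, and a Benjamini–Hochberg step at rate Q (default Q = 0.05%).
  Residuals below a 10⁻¹⁰ relative noise floor are treated as exact fits
  so floating-point jitter is never flagged.  Q = 0 disables removal.
* **Model comparison** uses the extra-sum-of-squares F test
  `F = ((SS₀ − SS₁)/(df₀ − df₁)) / (SS₁/df₁)`.  For the two-dataset
  radius-scaling comparison, radii are normalised to each dataset's value
  at a reference order (default 9) before fitting ln(radius) on order
  separately and pooled (2 constrained parameters).

## Skeleton correction

* **Multiscale smoothing** applies only to segments at or above a Strahler
  threshold (default order 6 — the published pipeline smooths the larger
  calibre; its figure panels disagree between "≥ 5" and "> 5", and the
  larger reading is the default with the threshold configurable).  Each
  interior point is replaced by a Gaussian-weighted average of the original
  points within an arc-length window of half-width `2 × local radius`
  (radius-proportional, hence "multiscale"), truncated symmetrically so
  straight uniformly sampled polylines are fixed points.  Endpoints and
  radii are untouched; topology is invariant.
* **Collapse detection** flags, within each order having at least 20
  segments, the segments whose mean radius falls below that order's lower
  percentile (default 10%).  Published descriptions of the rule ("below
  the 90% percentile") would flag 90% of segments if read literally; the
  sparse outliers actually marked in the corresponding figures imply a
  lower-tail rule, and the percentile is configurable.  The output is a
  candidate list: confirmation is a separate step (in the original
  workflow, a manual review; here, comparison against the generator's
  ground-truth manifest).
* **Radius restoration** samples, at every centreline point of a confirmed
  segment, a plane normal to the local tangent (central differences), finds
  the foreground component of the binary mask at the projected centreline
  point and assigns the equivalent radius `P / 2π` from the component's
  perimeter.  Points whose plane misses foreground keep their prior radius
  and are flagged; a segment where every plane misses is an error.
  Whether the original workflow replaced per-point radii or the segment
  mean is unstated; per-point replacement is used and the mean recomputed.

## Perimeters and cross-sections

Cross-section in-plane axes are fixed deterministically (the world axis
with the smallest |tangent| component crossed with the tangent, then
completed right-handed), so sections are bit-reproducible.  Binary and
label volumes are sampled nearest-neighbour to keep contours crisp; scalar
volumes trilinearly.

Perimeters are measured as the length of the marching-squares iso-contour
at level 0.5 of the component **mollified by a Gaussian of σ = 0.8 px**.
Raw binary contours overestimate a digitized disc's circumference by ~6%
(staircase bias); after mollification discs, squares and thin ellipses a
few pixels across or larger measure within ~2% of their analytic
perimeters, and the estimate is stable under sub-pixel translation.
Components too small to survive mollification fall back to the raw binary
contour; an isolated pixel measures 2√2 × spacing by that convention.

## Validation metrics

* Topological precision/recall thins both masks (3D skeletonization) and
  scores the fraction of each skeleton within a voxel tolerance of the
  other mask (skeleton-vs-mask in both directions, the common clDice-family
  reading).  Empty predictions score precision 0 with a flag rather than
  erroring, so batch sweeps do not abort.
* The 5-term super-metric compares a spatial graph against a reference
  mask: relative network-volume deviation (graph voxelized with its radii),
  |ΔCC|, |Δχ| (graph χ = components − independent cycles; mask χ = Euler
  number of the thinned mask), centreline sensitivity (fraction of graph
  points inside the mask) and bifurcation Dice.  Sensitivity and Dice enter
  the weighted sum as (1 − value); weights default to 1 and are echoed in
  results.  Mask branch points are found by a cut test — a skeleton voxel
  is a junction when removing the 3³ block around it leaves ≥ 3 skeleton
  components adjacent to the cut — with candidate clusters reduced to
  centroids; purely local neighbour counts miss junctions whose arms run
  diagonally side by side.  Graph-to-mask branch matching is greedy
  nearest-pair within a tolerance (default 2 voxels; fat-vessel fixtures
  need ~radius), each point matched at most once, ties broken
  lexicographically for determinism.

## Zonal analysis

Zone membership samples each centreline point at its containing voxel of
the label volume (labels: 1 cortex, 2 medulla, 3 hilum, 4 pillars,
0/off-grid outside).  A segment is assigned a zone only when all its points
agree (**unanimity**); any mixture is "crossing".  This is the reading most
consistent with excluding segments that span two regions, and it makes zone
segment counts sum to less than the organ total whenever crossings exist —
crossing segments still contribute to the organ-total row.  A majority rule
is available.  Whether membership should use centreline points or the full
lumen is an open question in the source material; centreline sampling is
the documented choice here.

## Synthetic data generator

The generator's defaults emulate the structure reported for an intact human
kidney arterial tree:

| parameter | default | rationale |
|---|---|---|
| topology | order_based | exact control of the Strahler order count |
| depth | 9 orders | observed order count of the whole-kidney network |
| branching_ratio | 2.9 | observed per-order count decay |
| radius_law | murray, exponent 3 | cube-conserving splits |
| asymmetry | 0.8 | child radius ratio; real networks deviate from symmetric |
| root_radius | 2900 μm | kidney-artery calibre |
| length_radius_ratio | 10 | organ-like chord lengths |
| tortuosity_amp | 0.2 | half-sine amplitude giving tortuosity ≈ 1.1 |

The order-based construction grows the tree top-down: each segment of order
ω ≥ 2 spawns `2 + Poisson(γ − 2)` children of order ω − 1, so the designed
orders coincide with computed Strahler orders and the **realized** fitted γ
is an emergent, seed-dependent quantity scattered around the target
(defaults produce trees of roughly 4–10 k segments with γ ≈ 2.7–3.0).
With `branching_ratio = 2` the construction is the deterministic full
binary tree (depth d → 2^d − 1 segments).  A level-growth topology is also
available (tips bifurcate with probability `branch_prob` per level, shed
terminal side twigs, or extend), for trees whose order counts are fully
emergent.

Geometry: child directions are sampled uniformly in a 40° half-angle cone
about the parent direction, resampled up to 10 times if the new tip lands
within two radii of an existing node (a cheap self-intersection guard —
segment-to-segment clearance is *not* checked, so dense configurations can
still overlap).  Chord length is `length_radius_ratio × radius`; with
tortuosity, interior points follow a half-sine of relative amplitude
`tortuosity_amp` in a random normal direction (amplitude a gives
tortuosity ≈ 1 + (πa)²/4; 0.2 → ≈ 1.1).  Murray radii split exactly
(`Σ rᵢ³ = r_parent³`, smaller children at ratio `asymmetry` to the
dominant child); the log-linear law sets `ln r` linear in Strahler order.

What the generator does **not** emulate: venous networks and capillary
beds, hemodynamically optimized geometry (CCO-style), anatomically
realistic spatial embedding within an organ capsule, radius noise along a
segment (radii are constant per segment unless perturbed), or imaging
artifacts beyond the provided perturbation operators (point jitter,
log-normal radius noise, vessel collapse by a fixed factor, terminal-branch
deletion).  Passing tests therefore demonstrate correctness of the
analysis operators under controlled statistical structure, not performance
on real organ-scale imaging with its segmentation errors and anisotropic
artifacts.

Voxelization stamps spheres along each sub-segment at half-voxel spacing
(a capsule union with linearly interpolated radii); the zone phantom is
nested spheres (hilum ⊂ medulla ⊂ cortex) with optional azimuthal wedges
of the medulla shell relabeled as inter-medullary pillars.

## Numerical and degenerate-input conventions

* Coincident segment endpoints make tortuosity undefined → error naming the
  segment.  Zero-length chords at junctions likewise error in angle
  computation.
* `order_counts` of an empty ordering is an empty table; single-segment
  graphs error in midpoint IVD (no neighbour exists).
* Standard deviations of size-1 groups are reported as 0 in summary tables.
* The pipeline recomputes ordering after skeleton correction before any
  statistics (correction can change which segments are outliers).
* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); identical config + seed reproduces
  byte-identical pipeline artifacts.

## Problem sizes in the test suite

The suite exercises the oracle comparisons at deliberately small scales:
random trees up to 500 segments (100 of them) against a recursive Strahler
oracle, exhaustive distance-transform checks on masks up to 16³, synthetic
organ-like trees at 5–7 orders (hundreds to low thousands of segments) for
recovery properties, and voxel fixtures of at most ~128³.  These sizes are
the package's choice of test fixtures; the operators themselves are
vectorized and handle the ~10⁴-segment scale of a whole-organ arterial
graph directly (the organ-scale ~500 GB image volumes themselves are out
of scope — analyses start from spatial graphs, masks and label volumes).

## Known limitations

* NRRD I/O is not provided; rasters travel as multi-page TIFF with voxel
  size metadata in the image description.
* Background-normalization of raw intensity volumes (a proprietary step in
  the workflow this package mirrors) is not implemented; pipelines accept
  pre-normalized volumes.
* The ROUT approximation is not bit-identical to the proprietary original;
  tolerances on outlier-sensitive statistics should allow for small
  membership differences.
* 3D thinning of fat tubes retracts free ends and can consume short wide
  branches entirely (and planar Y-junctions of fat tubes can thin into
  two-arm curves); skeleton-based validation metrics are most reliable when
  vessel radii are small relative to branch lengths at the chosen voxel
  size.
* Anisotropic voxels and block-wise processing of organ-scale volumes are
  out of scope.
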