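# Methods

## Problem and pipeline

The package estimates two architectural traits per orchard tree —
total height and crown volume — from survey data products, and
quantifies how well each estimation route tracks reference
measurements. Four routes are implemented.

**Raster routes (T1, T2).** A canopy height model is the cellwise
difference CHM = DSM − DTM, clamped at zero, with nodata propagated.
T1 uses a delivered terrain raster. T2 reconstructs the terrain from
point samples: ground locations are chosen (grid-stratified random by
default, rejecting crown footprints), their elevations are read from
the DSM cell containing them, and every cell is interpolated by inverse
distance weighting with weights d^(−p) over the k nearest samples
(defaults p = 2, k = 12, 100 samples; a cell within cell/10 of a sample
returns the sample exactly). The CHM is reclassified to a canopy mask
at a height threshold (default 0.5 m — the data give no principled
cut-off between canopy and understory clutter; it is exposed in the
config). Within each tree's manually defined extent rectangle, the
largest 8-connected canopy component defines the boundary in one of
three geometries: the polygon outline of the component's cells, their
axis-aligned bounding box, or the minimum enclosing circle of the
cell centers. Height is the maximum CHM value over cells whose centers
fall inside the boundary (standard zonal-statistics semantics: a cell
belongs to a zone iff its center does). Crown volume treats the crown
as a pyramid over the boundary footprint with effective height
0.80 × H: V = ⅓·A·(0.8H) for polygon/box, V = πr²(0.8H)/3 for the
circle. The 0.80 crown ratio is the fraction of total height above the
trunk and is a fixed constant of the method.

**Point-cloud route.** Exported clouds carry a small systematic tilt
(angular bias), so the first step is a rigid rotation that maps the
fitted ground-plane normal to vertical (details below). Statistical
outlier removal drops points whose mean distance to their k = 8 nearest
neighbors exceeds the global mean by 2 SD; the LiDAR preset adds voxel
down-sampling at 0.03 m (one centroid per occupied voxel). Trees are
segmented by half-open extent rectangles (min edges inclusive), keeping
ground points because H = Zmax − Zmin needs Zmin. The crown is the
sub-cloud with z ≥ Zmin + 0.20·H — per-tree, so residual terrain slope
does not shift the cut; 0.20 is the complement of the 0.80 crown ratio
and is used for both the UAV and LiDAR volumes. Crown volume is
measured two ways: the tetrahedral volume (Delaunay tetrahedralization
of the crown points, summing |det|/6 — identical to the convex-hull
volume, and cross-checked against `scipy.spatial.ConvexHull` in the
tests) and the voxel-grid volume (occupied voxels × voxel³ on a grid
anchored at the crown's minimum corner; default voxel 0.1 m). The UAV
route reports the hull volume, the LiDAR preset the voxel volume.

**Statistics.** Pearson r with two-sided p (sidedness is a convention
choice; two-sided is the default for correlation tests), significance
stars at p < 0.05 / 0.01 / 0.001 with boundary values falling in the
less-significant class, slope and intercept from an ordinary
least-squares fit, and R² reported as r² (identical for a simple linear
fit). Quartile summaries use inclusive linear interpolation (numpy's
default), fixed because violin-plot quartile conventions vary. One
anomalously large tree may be excluded before correlating (default
rule: the tallest tree of the second row), reducing n by one; a
17-tree LiDAR subset joins to n = 17 with no exclusion.

## Ground-plane fit and tilt correction

The tilt correction must recover a rotation of a few degrees from a
cloud in which canopy points outnumber ground points. A plain
least-squares fit to the lowest points of each 1-m horizontal block is
biased two ways: blocks fully under a crown contribute crown-flank lows
that sit decimeters above true ground, and one-sided lowest-point
selection attenuates the fitted slope whenever the coordinate noise is
comparable to the within-block relief (measured: 2.73° recovered from a
3.00° injected tilt). The implemented fit therefore (1) reduces each
block to the median of its lowest-decile points, so densely sampled
canopy blocks carry no extra weight, (2) iteratively trims block
representatives sitting more than 2.5 robust SD above the plane
(one-sided, so genuine low ground is never discarded), and (3) refits
on all cloud points inside a symmetric residual band around the plane,
shrinking the band from 0.2 m toward 3 robust SD but never letting it
grow. The symmetric final fit is unbiased under symmetric noise, and
crowns (≥ 0.4 m above ground for realistic trunk heights) stay outside
the band. The resulting rotation is applied about the cloud centroid —
a pure rotation, so pairwise distances and height differences are
preserved exactly; the recovered angle is stored in
`meta["tilt_correction_deg"]`. On sloped terrain the fitted plane
includes the terrain trend, so the correction levels the ground rather
than recovering the injected tilt alone — intended behavior for the
height computation, which wants Zmin and Zmax in a ground-referenced
frame.

## Synthetic orchard

The generator emulates the statistical structure of a small orchard
survey with exact ground truth.

- **Terrain**: a plane of configurable slope (default 0.01 m/m along x)
  about a mean elevation (700 m), plus an optional smoothed Gaussian
  field (default off). Cell size 0.05 m.
- **Trees**: default 20 trees in 2 rows (3 m in-row spacing, 4 m row
  spacing, ±0.15 m jitter). Total heights uniform on [2.13, 3.05] m —
  the range manual measurement tapes report for mature peach trees of
  this training system — and trunk height (1 − 0.80) of the total.
  The crown is a vertical half-ellipsoid seated on the trunk top
  (flat base), horizontal semi-axes uniform on [0.8, 1.3] m; its
  analytic volume ⅔πabc is the reference crown volume. The crown shape
  is a modeling stand-in: real peach crowns are not ellipsoids, so
  crown-volume agreement on synthetic data validates the estimators'
  geometry, not any allometric claim about peaches.
- **View-dependent sampling**: a view is an inclination (90° = nadir,
  65°, 45°) and a set of azimuths (default 4). Crown surface points are
  drawn on the half-ellipsoid (uniform directions on the upper
  hemisphere scaled to the ellipsoid — not exactly area-uniform, which
  is irrelevant here) and kept only if the outward surface normal has a
  positive dot product with the direction to the sensor for at least
  one azimuth. This normal-facing test is the cheapest mechanism that
  reproduces the real occlusion effect — nadir-only clouds miss crown
  flanks, oblique clouds see them — without ray casting; it does not
  model inter-tree occlusion or multi-bounce effects. Ground points are
  sampled outside crown footprints at one fifth of the crown density
  (sparse ground returns). Default density 300 points/m² of surface.
- **Noise and bias**: Gaussian coordinate noise (default sd 0.02 m) is
  added, then the whole cloud is rigidly rotated by the tilt angle
  (default 3°) about a horizontal axis through the centroid.
- **Raster products**: the DSM is the per-cell maximum z with empty
  cells nearest-filled. The surface/terrain rasters are built from
  bias-free twins of the same random draws (same seed, zero tilt),
  reflecting that the angular bias afflicts exported point clouds, not
  georeferenced raster products; the point-cloud route receives the
  tilted clouds and must correct them.
- **Integrated dataset**: the union of the per-view clouds, mirroring
  multi-angle photogrammetric processing.
- **LiDAR preset**: a ground-level scan emulation — low inclination
  (30°), 8 azimuths, double density, half noise — covering only the
  first 17 trees (partial acquisition), processed with voxel
  down-sampling.

What passing synthetic tests shows: the estimators recover known
geometry through the full pipeline, the occlusion mechanism has the
expected direction, and accuracy degrades monotonically with noise.
What it does not show: robustness to photogrammetric reconstruction
artifacts (doming, texture-dependent dropouts), real understory
vegetation, wind-blown foliage, or non-ellipsoidal crowns.

## Numerical choices and degenerate inputs

- Rasters are row-major from the north-west origin with half-open
  cells; all segmentation extents are half-open on their max edges, so
  adjacent extents partition points without double counting.
- The polygon boundary is unioned on the integer cell grid and then
  affine-mapped to world coordinates; unioning floating-point cell
  rectangles leaves undissolved slivers (adjacent corners differ in the
  last ulp) and silently fragments the boundary.
- The minimum enclosing circle is built on component cell centers
  (shapely's exact implementation). Consequence: for round components
  the polygon (which includes each cell's half-cell fringe) can
  slightly exceed the circle's area; only polygon ≤ box is a universal
  ordering.
- Voxel counts depend on the grid anchor by at most one surface shell
  of voxels; the anchor is fixed at the crown's minimum corner and the
  shell bound is asserted in tests.
- Hull volume requires ≥ 4 non-coplanar points; coplanar crowns raise
  a degenerate-geometry error rather than returning 0. IDW requires
  ≥ 3 in-extent samples. Correlation requires n ≥ 3 and nonzero
  variance. Empty segmentation extents raise errors naming the tree.
- Determinism: every stochastic component takes a seed; the pipeline
  derives per-view seeds by fixed offsets, and identical configs
  produce byte-identical CSV reports.

## Problem sizes

The default pipeline (20 trees, 300 points/m², 0.05 m cells) runs in
about half a minute on one core. The test suite and the acceptance
script use that default for the zero-noise recovery check, a reduced
density (150 points/m²) for the 30-run noise-degradation study, and
reduced tree counts for unit-level checks — sizes chosen to keep the
full validation loop interactive while leaving every mechanism
exercised at realistic densities.

## Known limitations

- Crown volumes from the pyramid formulas and from the point-cloud
  estimators are on different geometric conventions (pyramid over a
  footprint vs hull/voxel of the actual crown); they are compared to
  reference via correlation, not absolute agreement.
- The voxel-grid volume overestimates convex solids by up to a surface
  shell; the hull volume underestimates them (inscribed polytope); both
  biases shrink with density and are bounded in tests.
- The occlusion model is per-point normal-facing only; it cannot
  produce the inter-tree shadowing a real oblique flight sees in dense
  canopies.
- `.pcap` LiDAR ingestion is out of scope: convert captures to XYZ CSV
  externally before processing.
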