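# Methods

## 3D reconstruction and morphometrics

**Projection model.** The seed (≤ 0.6 mm) is far smaller than the
working distance of a macro 3D station, so projection is modelled as
orthographic with a fixed µm/px scale. The rotation axis is a vertical
image column, taken from calibration or estimated as the median
silhouette-centroid column over the rotation series (exact for a solid
of revolution, adequate for seeds).

**Silhouette segmentation.** Views are backlit, so the seed is the dark
phase of an Otsu split. Exactly one large connected component is
expected; zero raises an empty-view error and several raise an
ambiguity error carrying the count. Holes are filled (a silhouette is
simply connected).

**Carving.** A voxel is occupied iff its *center* projects inside the
silhouette in every view (center test; a corner-conservative test would
systematically dilate the hull). The result is the visual hull: the
maximal shape consistent with all views, hence an over-approximation of
the true seed whose error shrinks with voxel size — the suite checks
volume error decreases monotonically over 20 → 10 → 5 µm voxels. The
default voxel edge is 5 µm, resolving the smallest semi-axis of an
Arabidopsis seed (~0.135 mm) into ≥ 27 voxels; a warning is emitted
below 20 voxels of span. Concavities (the seed groove) are invisible to
any silhouette method and are not recovered.

**Surface area.** Counting voxel faces overestimates a sphere's area by
roughly 50%, so the occupancy grid is smoothed with a Gaussian of
σ = 0.8 voxel and the 0.5 iso-surface is meshed with marching cubes.
σ was calibrated on analytic spheres: 0.8 keeps spheres of 0.125–0.275
mm radius within 1% of 4πr² while rounding a cube's edges by only
~2.3%; larger σ improves spheres marginally but erodes edges and small
caps.

**Length, width, height.** Length is the longest in-object distance,
found as the farthest pair over the convex-hull vertices of surface
voxel centers (the diameter of a point set is attained on its convex
hull, so the O(k²) search runs on a few thousand points, not the whole
hull). Width is the farthest pair after projecting those vertices onto
the plane orthogonal to the length axis; height is the extent along the
remaining orthogonal direction; width ≥ height is enforced by a swap.
Extents are center-to-center distances of boundary voxels, which
roughly offsets the half-pixel dilation inherent to the visual hull;
the suite requires agreement with analytic solids within one voxel plus
one rendering pixel.

**Occlusion extrapolation.** When the top of the seed is hidden inside
the nozzle, every view is truncated at the same physical plane and the
carved hull ends in a flat face. The visible *lateral* surface voxels
(the flat face excluded) are fitted with an algebraic least-squares
quadric; the fit is converted to centered ellipsoid form and refined by
Levenberg–Marquardt on the normalized residual ‖L(p−c)‖−1 (the
algebraic fit alone is biased toward smaller caps when only part of the
surface is observed). Voxels above the plane are then filled where the
fitted ellipsoid contains them, restricted to the (dilated) contact
cross-section — for any convex seed truncated at or above its widest
section the missing cap lies inside the cylinder over the contact
cross-section, so this bound cannot remove true cap volume. Recovery is
validated by synthetic truncation: a sphere with 10% of its height
hidden is recovered within 2% of the analytic volume, a half-hidden
prolate ellipsoid within 10%. If the fitted quadric is not an ellipsoid
(degenerate data) the hull is returned unchanged with a warning rather
than guessing.

## 2D traits

Brightness is the mean HSV value (hexcone model, reported in % of full
scale) of a 5×5 px patch centered on the mask centroid — a
pixel-defined cutout (≈ 80×80 µm at 16 µm/px) that avoids the dark rim
of the seed while retaining surface variation, with the patch shrunk
and flagged when it would leave the mask. Projected area is the pixel
count times the pixel area; values outside 0.05–0.5 mm² are flagged as
implausible for a single Arabidopsis seed rather than rejected. The
mass model `m = a·A^{3/2}` follows from geometric similarity (mass ∝
length³, projected area ∝ length²); the fit is linear least squares in
`A^{3/2}` and reports per-seed relative deviations, which on real seeds
are known to be large — the model ranks seeds, it does not weigh them.

## Tray grid and cropping

Pot-wall crossings are found by correlating the greyscale tray image
with a zero-mean plus-shaped kernel at the expected wall width: a 4-way
inner crossing matches all four arms whereas border T-junctions match
three and score lower, so after non-maximum suppression (at 0.4× the
pot pitch) and exclusion of a border margin the strongest
(n_cols−1)(n_rows−1) peaks are the inner crossings. Grid lines are
least-squares fitted per family; the border lines are extrapolated at
the mean line spacing (uniform pot pitch). The lattice keeps the
*measured* crossings as its inner nodes — trays flex, and the observed
points beat the straight-line smoothing there — while the outer ring
comes from the fitted lines. Crop boundaries are straight segments
between adjacent lattice nodes, so the cells partition the tray exactly:
every pixel is assigned to one cell by comparing against the boundary
polylines. Outer nodes inherit the (unobservable) jitter of the tray
border, so their error grows with jitter amplitude even when inner
crossings are localized within a pixel; plants sit inside pots, so
cropping is insensitive to this.

## Growth fitting

Leaf area is green-pixel count × 0.0013 mm²; a pixel is green under HSV
gates (hue 60–180°, saturation > 0.25, value > 0.15, configurable).
Emergence (operational germination) is the first observation with ≥ 10
green pixels. Cotyledon growth is expansion-dominated and near-linear;
exponential growth starts with the first true leaves — so the early
phase is identified *backwards*: starting from the full post-emergence
series, exactly one trailing point is removed per iteration until a
linear OLS fit satisfies all of adjusted R² > 0.9, slope and intercept
two-sidedly significant at α = 0.05, and deviance (residual sum of
squares, Gaussian model) per point < 0.1 (mm²)². The accepted segment
is therefore the longest qualifying prefix; its slope is the early
growth rate and its x-intercept the germination time (clamped at sowing
with a flag if negative). α and the minimum segment length (4 points,
leaving 2 residual degrees of freedom) are conventional defaults; a
numerically perfect line is accepted with p = 0 by convention. Series
that never qualify get status `no-linear-fit`, and series that never
emerge `no-emergence` — status flags stand in for the manual validation
a production pipeline would still apply. The exponential `A₀·e^{rt}` is
fitted by nonlinear least squares over all post-emergence points,
initialized from the log-linear regression.

## Statistics

*Kinematics.* Pneumatic release: `a = πr²p/m`, `v = √(2ad)` (5 mm
travel). Hammer release: the hammer reaches `√(2gh)` after its ~1 mm
drop and a perfectly elastic collision with a much lighter seed passes
on at most twice that — both speeds are reported; no energy losses are
modelled.

*Old-balance simulation.* Around each precise mass a normal with SD =
15% of the value is built and 100 values drawn; the inflated sample's
SD converges to √(SD² + (0.15·mean)²).

*Minimal n.* Batches are treated as fixed distributions (mean, SD).
For each candidate n the equal-n two-sample t statistic is compared
with the t critical value at α = 0.05 (two-sided, Welch degrees of
freedom — the batch SDs differ markedly, so the unequal-variance
flavour is used throughout); the smallest significant n is returned.
The resampling variant emulates the measured batches as normal samples
standardized to the summary's exact mean/SD (the batch data are one
fixed observation; only the balance-noise emulation is stochastic),
inflates them, and reports the mean and mode over seeded repetitions.
Equal means return a no-finite-n sentinel (None).

*σ confidence intervals.* From the single-sample chi-square pivot,
bounds √((n−1)/χ²) at the 2.5/97.5% quantiles; the width is reported in
integer percent of σ. Width is strictly decreasing in n — the practical
reading being that ~100 seeds estimate σ to about ±14% and doubling to
200 buys little.

*Correlations.* Pairwise-complete Pearson r with significance stars at
p < 0.05/0.01/0.001 and no multiplicity correction; constant traits
yield missing entries. Hue and saturation are computed but no claims
attach to them.

## Synthetic data: what it emulates, what it does not

Generators return machine-readable ground truth and are bit-reproducible
given a seed. Shapes are convex analytic solids (spheres, ellipsoids,
superellipsoids) rendered by exact ray tests — they validate the
carving geometry but carry none of a real seed's grooves, mucilage or
specular edges, so passing tests bound geometric, not photometric,
error. Tray images have uniform-noise soil, straight bright wall
segments between jittered lattice nodes (jitter up to 3 mm, the stated
fabrication inaccuracy) and green blobs of exact pixel counts; real
trays add moss, reflections and overgrowth the detector is not tested
against. Growth curves are zero before germination, linear to the
switch, exponential after (value-matched at the switch, so the slope
may be mildly discontinuous — consistent with fitting the exponential
to all points), with additive Gaussian noise clipped at zero. Defaults
are the control-batch estimates (germination 3.77 d, rate 1.02 mm²/d)
with a 0.5 /d exponential rate — mid-range of reported Arabidopsis
seedling leaf-area RGR — starting ~4 d after germination, and daily
sampling over 14 d. Trait batches are multivariate normal (scatter of
real trait pairs is near-elliptical) truncated at zero, with a default
correlation structure in which mass and volume are nearly collinear
(r = 0.98), both couple moderately to the linear extents, width and
height couple to each other but not to length, length is
anti-correlated with sphericity, and brightness with germination time.
Real batches deviate from joint normality in the tails; moment and
correlation recovery is what the tests certify.

## Problem sizes and determinism

The test suite carves at 5 µm voxels (grids ≈ 110³), uses 200
replicate growth curves for parameter recovery, 1000 repetitions for
the resampled minimal n and type-I-error checks, and 10 jittered trays
for the cropping comparison — sizes chosen so the full suite runs in
well under a minute on one core while keeping Monte-Carlo error far
below the asserted tolerances. All randomness flows through explicit
`numpy.random.default_rng` seeds; property-based tests are
deterministic.

## Known limitations

- The visual hull cannot recover concave features; volumes of grooved
  seeds are slight over-estimates by construction.
- Occlusion extrapolation assumes the hidden cap is ellipsoid-like;
  strongly non-ellipsoidal tips (beaked seeds) would be mis-extrapolated,
  bounded by the contact-cylinder cap.
- The crossing detector assumes walls brighter than soil and pots in a
  regular layout; heavily overgrown trays (plants covering crossings)
  are out of scope.
- The mass-from-area model and the density gate are plausibility tools,
  not measurements.
- Leaf counting, rosette shape and developmental staging are out of
  scope, as is any instrument control.
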