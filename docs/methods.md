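# Methods

This note documents the models implemented in `fcdq`, the parameter
defaults and why they were chosen, what the synthetic data do and do not
emulate, and the numerical decisions taken where the design was open.

## Coordinate conventions

Map coordinates are millimeters with lambda at the origin, x lateral
(midline 0) and y anterior-positive; bregma sits 4.2 mm anterior of
lambda.  Rasters are row/column with origin top-left; pixel landmarks are
(x = column, y = row).  Microscopic data use micrometers.  Bins are
half-open [lo, hi).  SWC radii are doubled into diameters on read.

## Lesion topography

**Registration.**  Masks are mapped into atlas space by a similarity
transform (scale, rotation, translation) fitted by the closed-form
least-squares (Umeyama) solution to the bregma→bregma, lambda→lambda
landmark correspondence; with exactly two landmarks the fit is exact.
Reflections are excluded, so image pixel coordinates are flipped to a
y-up frame before fitting.  The map-space raster is fixed at 0.02 mm/px
and masks are resampled by nearest neighbor: binary masks stay binary,
the procedure is deterministic, and for lesions of a few mm² the area
error is well under 2% (verified in the tests).

**Predictors.**  Lesion area is pixel count × (0.02 mm)²; the frontal
edge is the anterior-most mask pixel's AP coordinate relative to lambda,
measured on the projected (map-space) mask so all animals share one
frame; LSI = sqrt(area) + frontal edge, which weighs a doubling of area
like ~1 mm of anterior displacement at typical lesion sizes.  Per-area
coverage is the fraction of each atlas polygon intersected by the mask;
domain-level coverage is the unweighted mean over member areas (the
aggregation is not otherwise pinned down; area-weighted means differ
only when member areas differ strongly in coverage).

**Seizure model.**  Logistic regression is fitted by damped
Newton–Raphson (tolerance 1e-10 on the step norm, at most 100
iterations, step halving whenever a step would decrease the
log-likelihood).  The likelihood-ratio test compares against the
intercept-only model (χ², 1 df).  Complete separation is detected
either by coefficient divergence (‖β‖ > 10³) or by the log-likelihood
saturating at its perfect-classification asymptote of 0; separated fits
are flagged and their coefficients are reported as unreliable.  Accuracy
is in-sample at the p > 0.5 cutoff — no cross-validation, matching the
small-cohort usage the model mirrors.  Note that the in-sample accuracy
of a converged MLE can, for uninformative predictors, fall marginally
below the majority-class rate; the MLE maximizes likelihood, not 0/1
accuracy.

## 3D cell counting and classification

The counting scheme assumes approximately spherical somata segmented
per-frame into instance masks.  Parameters (defaults): downsample 4
(3.2 µm coarse pixels at 0.79 µm/px), persistence threshold 4 frames,
margin 5 frames excluded at either end of the stack (so cells straddling
consecutive sub-stacks are not counted twice), k-means with k-means++
init, 50 restarts, caller-provided seed.  Coordinate rounding in the
accumulator is half-away-from-zero (deterministic).  Ties for the
largest member-mask area break toward the lower frame index.  The
ellipse is the second-central-moment (equivalent-inertia) ellipse of the
largest cross-section; the effective diameter is the equal-area value
sqrt(major·minor).  The detection centroid takes x/y from that
cross-section and z from its frame index — for spheres the largest
cross-section is the equator, so the z error is bounded by the Z-step.

A structural limitation inherited by design: two cells at the same XY
location within one analyzed sub-stack collapse onto the same
accumulator cell and cannot be distinguished.  The generator therefore
supports an XY-projection separation constraint, used by the
count-recovery experiment; real stacks thin enough for the margin rule
(tens of µm) rarely stack somata vertically.

**Intensity measures.**  Two are provided.  The slice-wide 2D measure
follows the MIP workflow: maximum-intensity projection, contrast stretch
mapping the 1st/99th percentiles to 0/255, mean over the fitted ellipse.
The 3D measure averages the intensity over all member-mask voxels of a
detection and is the default filled in by `detect_cells_3d`: the MIP of
noisy frames inflates means by extreme-value statistics (≈ 2 noise SD
for cells spanning ~15 frames), which matters when thresholds derived
from cell intensities are compared against thresholds derived from
background statistics.

**Thresholds.**  The bi-Gaussian method histograms cell mean intensities
into 256 bins over 0–255 and fits a two-Gaussian curve to the bin counts
by nonlinear least squares (means initialized at the 25th/75th
percentiles, SDs at half the sample SD, amplitudes at the max count,
at most 10⁴ evaluations); the threshold is the midpoint of the fitted
centers.  Fits that do not converge, or whose centers land within 2 bins
of each other, raise a "unimodal" error directing callers to the
background method — by construction the bi-Gaussian route only applies
to lesion-bearing slices with two populations.  The background method is
factor × mean intensity over manually placed first-layer points
(defaults 3.0 for pS6, 1.5 for GFP/NeuN).

The threshold-agreement experiment (`validation.threshold_agreement`)
uses populations at 178/187 a.u. with SD 1.5 (exactly 6σ separation)
over a background of 178/3 ≈ 59 a.u.  These values were chosen
analytically from the agreement bound itself: the midpoint (µ₁+µ₂)/2
can only sit within ±5% of 3× background = µ₁ when
(µ₂−µ₁)/(µ₂+µ₁) ≤ ~5%, i.e. for narrow populations that are close in
relative terms but still cleanly bimodal.  This mirrors the regime in
which the two methods were observed to interchange in practice.

**Other measures.**  Tangential lesion extent trims a fixed fraction
(default 1%) of cells on each side by the nearest-rank quantile rule.
Cortical thickness is the distance from a surface point along the inward
surface normal (averaged over the two adjacent polyline segments) to the
first intersection with the gray/white-matter boundary; thickening is
the percent excess over the homotopic contralateral thickness.
Counting volume defaults to analyzed area × (frames − 2·margin) × Z-step.

## Bouton morphometry

The diameter profile is analyzed on the exported node grid without
resampling or smoothing.  The shaft caliber is the 5th percentile
(linear-interpolation quantile) of node diameters — robust as long as
thickenings occupy well under 5% of nodes.  The relative profile is
r(s) = d(s)/d_shaft − 1, so the acceptance thresholds read as fractions
of the shaft: minimum height 0.2 (20% above shaft), minimum topographic
prominence 0.1, minimum arc separation 1 µm (conflicts resolved in favor
of the higher peak, iteratively).  Width is the arc extent where r stays
above half the peak's height, with linear interpolation at the
crossings and clipping at the profile ends.  Bouton volume treats the
peak diameter as the two equatorial diameters and the width as the polar
diameter of a rotational ellipsoid, V = (π/6)·d²·w; if those lengths
were instead read as semi-axes the volume would be 8× larger — the
printed group medians cannot discriminate the two readings, so the
diameter reading (which keeps a 1-µm spherical bouton at ~0.52 µm³,
the physiologically familiar value) is used.

## Depth profiles

The brain surface is the convex hull of all detections.  The depth axis
is anchored at the hull point nearest the lesion center of mass (mean of
lesion-channel positions) and directed along that facet's inward normal;
the column is 1 mm × 1 mm square, perpendicular axes fixed by a
deterministic rule.  Depths are binned at 0.01 mm, rescaled by the
95th-percentile in-column depth (a robust proxy for the local cortical
depth extent), resampled to 100 relative-depth bins and normalized to
unit sum.  PCA of curve shapes uses the SVD of the column-mean-centered
animal × bin matrix; PC1's sign is fixed by making its loading at the
shallowest bin non-negative; groups are compared by a two-sided
Mann–Whitney test on PC1 scores, with the degenerate all-identical case
reported as p = 1.  Because the axis is anchored on the hull, the depth
origin is effectively the shallowest detected cells near the lesion — a
channel with no superficial label would shift all depths by its own
offset (this is why the synthetic lesion channel includes surface-depth
points; see below).

## Statistics kernel

Mann–Whitney U uses the exact null distribution when n₁·n₂ ≤ 400 and no
ties are present (a tractable enumeration bound), otherwise the
tie-corrected normal approximation with continuity correction; the
implementation delegates to scipy and is cross-checked in the tests
against brute-force enumeration of label assignments.  Bonferroni
adjustment is min(1, p·m).  Quantiles use the linear-interpolation
(type-7) rule throughout.

## Synthetic data: what it emulates, and what it does not

The generators draw every random quantity from one seeded
`numpy.random.default_rng` per call; fixed seeds reproduce outputs
bit-for-bit.

* **Cohorts** draw frontal positions and areas from normal distributions
  with center = printed group median and spread = printed IQR/1.349
  (seizing 7.4 [6.5–7.8] mm, n = 12; non-seizing 6.1 [5.6–6.4] mm,
  n = 14; areas 10.2 vs 6.8 mm², common spread 4 mm²).  Lesions are
  ellipses with a fixed 1.3 AP:lateral aspect ratio — a modeling choice,
  not a claim about real lesion shapes — rasterized under a per-animal
  random similarity (±5° rotation, 0.95–1.05 scale) so registration has
  real work to do.  Truth areas/edges are measured from the ellipse
  rasterized on the common map grid, hence exact for scoring and
  convergent to the analytic values as the grid is refined.
* **Cell stacks** are non-overlapping spheres with per-population
  diameters (defaults 15 vs 24 µm, matching baseline vs mTOR-hyperactive
  neuron sizes) and per-cell intensities around population means, plus
  Gaussian pixel noise, clipped to the 8-bit range.  Frames are exact
  circle cross-sections — no point-spread function, no segmentation
  errors, no touching cells.  Passing tests therefore show the counting
  pipeline is correct given correct instance masks, not that upstream
  segmentation is.
* **Axon traces** superpose Gaussian bumps (σ = FWHM/2.355) on a
  constant shaft.  Noise is multiplicative with a 1 µm correlation
  length (white noise smoothed and rescaled): diameter estimates from
  imaging share optical support between submicron-spaced nodes, so
  independent per-node noise would be unphysical — and would also make
  any fixed height threshold unusable, since the 5th-percentile shaft
  estimate sits ~1.6 SD below the true caliber under heavy-tailed
  per-node noise.  Detection experiments lay out bumps at the linear
  densities observed on real axons (~0.2/µm).
* **Point clouds** sample relative depths from a tabulated density and
  embed them under a paraboloid dome (default curvature 0.1/mm, keeping
  the dome sag across the 1-mm column below one resampled depth bin).
  The lesion channel is a compact cluster whose label spans the surface
  to mid-depth; the truth curve is the input density re-expressed on the
  pipeline's output axis (rescaled by the density's own 95th
  percentile), so recovery is scored on commensurate scales.

## Experiment sizes

The recovery experiments use 20 slices (threshold agreement), 200
stacks of 5–50 cells (count recovery), 200 traces per noise level
(bouton precision/recall), 500 cohort replicates (direction recovery),
1000 null fits (logistic calibration), 300 replicates of 10 vs 10
animals (PC1 null calibration), and 10⁴ null simulations at n = 14 per
group for the Mann–Whitney type-I rate — a size at which the exact
test's discrete achievable level (0.0497) essentially matches the
nominal 0.05.

## Known limitations

* The atlas is a schematic rectangular tiling: area names, adjacency
  order and domain grouping are faithful; shapes and exact extents are
  not, so absolute coverage fractions are not comparable to values
  measured on a real atlas.
* Landmark-based registration replaces interactive warping;
  with more than two landmark pairs it becomes least-squares, but no
  nonlinear deformation is supported.
* The depth-profile χ²-flatness check is mildly anticonservative
  because the depth scale is estimated from the same sample.
* All densities and fractions inherit the counting-volume convention
  (analyzed area × analyzed depth); other conventions rescale densities
  by a constant factor.
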