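# Methods

`spinemetrics` implements three computational assays for small-fish spine
imaging — automated vertebral-centra segmentation with relative-density
statistics, 3D osteocyte-lacuna morphometrics, and a radiograph
density/disc-morphology correlation — together with seeded phantom
generators that provide ground truth for every stage.  This note records
the models, the operational choices behind them, and what the synthetic
validation does and does not demonstrate.

## Conventions

All 3D arrays are `(z, y, x)` with `z` the anteroposterior axis.  Voxel
sizes and point coordinates follow the same ordering; CSV outputs label
columns `z_um`/`y_um`/`x_um` explicitly.  All lengths are micrometres,
densities are image grayscale unless calibrated to g·cm⁻³ CaHA.  Every
generator draws from a single `numpy` generator seeded from its spec, so
identical specs give bit-identical phantoms.

## Spine segmentation

The chain reduces a µCT reconstruction to per-centrum density statistics:

1. **Downsample** by 0.5 (local block mean; the general path uses linear
   resampling for non-reciprocal factors).  Output dimensions are
   `round(dim x factor)` and voxel size scales by `1/factor`.
2. **Threshold to a sparse cloud.** The brightest
   `ceil(retained_fraction x n_voxels)` voxels are kept as `(z, y, x,
   intensity)` quadruplets; ties break in raster order so the operation is
   a pure function of the volume.  The default fraction 0.007 (brightest
   0.7%) reflects the bone content of a whole-fish scan; for phantoms the
   matching condition is the phantom's own bone-volume fraction, which the
   pipeline uses automatically when the config does not pin a value.
   Reading the threshold as "intensity above the 0.7 quantile" instead is
   available by setting `retained_fraction = 0.3`-style values; the
   brightest-fraction reading is the default because bone is the sparse
   bright phase.
3. **Head removal.** Points are binned along the cloud's first principal
   axis into equal-width bins (default 2 voxels wide).  A terminal
   contiguous run of at least two bins whose counts exceed
   `head_density_ratio` (default 2) times the median occupied-bin count is
   taken as the head; the cut then advances to the first empty bin so the
   blob's sparse taper goes with it.  Two bins minimum matters: binning
   voxel-spaced slices can alias a single fat bin anywhere, but a real
   blob spans many bins.  Without a qualifying run the cloud passes
   through unchanged.
4. **Axis fit.** Intensity-weighted transverse centroids per axial bin
   (4 voxels wide), then a smoothing cubic B-spline through them.  The
   smoothing parameter is a per-centroid residual budget, default one
   voxel squared: a straight phantom yields a straight axis (its centroid
   residuals are ~0) while a gentle lateral bow is still followed; a much
   larger budget would flatten the bow.  The fitted curve is discretized
   to a fine polyline (step ~ voxel/4) extended ~1.5 profile bins past the
   terminal centroids so points at the cloud's ends do not clamp onto one
   arc position.
5. **Curvilinear profile.** Each point contributes its intensity to the
   arc-length bin of its nearest polyline vertex; total profile density
   equals total cloud intensity exactly (a conservation property the tests
   assert).
6. **Spacing detection.** Intervertebral spacings are minima of the
   profile found by peak-finding on the inverted profile with (a) a
   prominence of at least `peak_prominence` (default 0.1) times the
   profile's dynamic range, (b) mutual separation `peak_min_separation_um`,
   and (c) a relative-depth criterion: the minimum must lie below
   `spacing_depth_ratio` (default 0.35) of its lower flanking maximum.
   The third criterion is what separates true spacings from the waist of
   an hourglass centrum regardless of that centrum's absolute density:
   spacings contain essentially background, while the waist only dips to
   roughly half of its endplate peaks.
7. **Label spreading.** Points within the central `core_fraction`
   (default 0.5) of each inter-boundary arc segment are seeded with that
   segment's label; remaining points are labeled by a deterministic
   k-nearest-neighbour wavefront (k = 12): each pass labels every point
   with at least one labeled neighbour by majority vote, ties resolved by
   smaller mean neighbour distance, then lower label.  A disconnected
   remainder falls back to nearest-labeled-point assignment, so labeling
   is total and repeat runs are identical.
8. **Statistics.** Per-centrum mean intensity; relative density scaled by
   a reference-group mean (or the sample's own mean, making the average
   relative density exactly 1); within-sample SD of centrum means as the
   mineral-heterogeneity readout.  Tissue mineral density comes from the
   exact two-point affine map through the 0.25 / 0.75 g·cm⁻³ CaHA phantom
   grayscales; extrapolation beyond the anchors is allowed and logged.

Rib-bearing abdominal centra are excluded in the source protocol by
anatomy; phantoms have no ribs, so the equivalent here is an arc-length
exclusion window applied by the caller if needed.

## Lacunar morphometrics

Lacuna candidates (binary masks or probability maps from any upstream
classifier) are binarized at `binarize_threshold`, labeled with
26-connectivity (6 available), filtered to `lacuna_size_filter_um3`, and
discarded when their centroid falls outside the bone mask.  Per object:

- **Ellipsoid fit** by second moments: covariance eigenvalues of a solid
  ellipsoid are a²/5, b²/5, c²/5, so semi-axis i = √(5 λᵢ) exactly; the
  major axis is the leading eigenvector, sign-normalized.  Coplanar or
  tiny objects are flagged degenerate rather than fitted.
- **Sphericity** = π^(1/3)·(6V)^(2/3)/A with V = (4/3)πabc of the fitted
  ellipsoid and A the Knud Thomsen surface-area approximation
  (p = 1.6075, max error ~1.1%); exactly 1 for a sphere, strictly below 1
  otherwise.  The tests check it against a numerical surface-quadrature
  oracle.
- **Orientation** = angle between the major axis and the radial direction
  from the centrum center, folded to [0°, 90°].  The radial convention is
  a choice — the source protocol fixes only the reference point.
- **Nearest-neighbour distance** (centroid-to-centroid, exact via a k-d
  tree) and **surface distance**: the bone surface is the layer of bone
  voxels 6-adjacent to background, and the distance is the exact
  Euclidean distance transform of that layer's complement at the
  centroid.  This definition makes the center of a 21-voxel bone cube lie
  10 voxels from the surface (not 11 to the first background voxel).

Summary statistics: lacunae per µm³ of bone and the mean volume of the
⌈M/4⌉ smallest lacunae ("smallest-quartile volume").  The 2D
mineralization-robustness measurement binarizes an orthoslice and reports
% foreground in four square ROIs anchored at the corners of the centrum's
bounding box — a stand-in for "the four vertices of the centrum", which
the source does not define geometrically; CV across repeated slices
quantifies within-sample heterogeneity.

## Radiograph profile analysis

A profile is the mean intensity across a 40-pixel-wide band along a line
through 7 vertebrae.  Profiles are first rescaled by the affine map
sending the measured calibration-phantom patch means to the fixed
reference pair (0.25, 0.75), removing per-image exposure gain and offset.

**BMD** is the trapezoidal integral of the background-subtracted profile
divided by the line length.  The background is a least-squares line
through the profile's local minima; operationally, the `n_vertebrae - 1`
most prominent strict minima of the lightly smoothed profile (window 3,
configurable), fitted on the smoothed values.  A line through k vertebrae
crosses exactly k−1 disc spaces; without that constraint, noise-induced
dimples on the peaks' flanks enter the fit and displace the background
line by far more than the noise amplitude.  Fewer than two minima fall
back to a global-minimum constant.

**Morphological similarity** is the peak over all lags of the full
(zero-padded) cross-correlation with the wild-type standard profile,
rescaled by the peak of the standard's autocorrelation — exactly 1 for a
profile identical to the standard, tolerant of small translations.
Profiles are linearly resampled to the standard's grid and are *not*
mean-subtracted (the autocorrelation normalization already yields 1 for
identical raw profiles); a `mean_subtract` flag enables the variant.
Values above 1 occur when a sample's amplitude exceeds the standard's and
are reported unclamped with a log note.  The cohort statistic is the
Pearson correlation between BMD and similarity with the two-sided
t-transform p-value.

## Synthetic phantoms

**Spine phantom.** Hourglass-profiled centra (endplate radius R narrowing
to (1−0.35)·R mid-centrum) stacked along a laterally bowed axis
(amplitude = `axis_curvature` × R over a half-sine), separated by
background-intensity gaps so the axial profile has true minima at the
spacings; per-centrum constant densities; an optional head blob — a solid
ellipsoid brighter than any centrum with a wider cross-section, giving it
more than twice the spine's thresholded point density; additive Gaussian
noise.  Defaults (20 centra of 54 µm, 36 µm gaps, 6 µm voxels, R = 60 µm)
put the downsampled analysis grid near 165x64x64 — a desk-scale model of
an adult-zebrafish spine scan.  Truth: per-voxel labels, per-centrum
densities, arc-length gap positions, and the generating curve.

**Lacunae phantom.** Non-overlapping voxelized ellipsoids (rejection
sampling with a minimum separation exceeding twice the largest semi-axis)
inside a bone slab with a background border; truth carries centroids,
semi-axes, sign-normalized major axes and analytic volumes (4/3)πabc.
Default ranges give ≥ 8 voxels per semi-axis, the regime in which moment
fitting recovers axes to a few percent.

**Radiograph cohort.** Each fish's profile is a 7-peak Gaussian template
scaled by its density b, plus a linear background, per-fish exposure gain
and offset (undone downstream via the phantom patches), and noise.  The
density-morphology coupling maps the relative density excess to a
deformation d = `coupling_strength`·(b−baseline)/baseline that (i) moves a
fraction min(0.85, 0.5·d) of each peak's mass symmetrically onto two
sub-peaks 1.5 peak-widths toward the endplates — modeling endplate-biased
mineral redistribution — and (ii) shifts each peak along a fixed
per-vertebra pattern scaled by 0.05·period·d.  The symmetric split is the
load-bearing choice: it cannot be undone by any global lag (so the
lag-maximized cross-correlation decays linearly in d), and it leaves the
inter-vertebral valleys clean (so BMD keeps tracking b).  Width-only
deformations fail on both counts in this statistic: area-preserving
widening floods the valleys and the minima-fit background then swallows
the BMD signal, while constant-amplitude widening *increases* the
unnormalized cross-correlation.  The coupling saturates once the mix
fraction caps at 0.85 (d ≈ 1.7); within the default density range
(1.0–1.28 × baseline) similarity is strictly decreasing in b on noise-free
cohorts, which the tests assert.  The coupling is an explicit stand-in,
not an estimate of disc biology — no quantitative morphology-deformation
model for degenerated discs exists to copy.

## What the phantoms do and do not show

Phantoms have constant-density centra, exact ellipsoids, Gaussian noise,
and no beam hardening, ring artifacts, ribs, arches, or partial-volume
texture beyond block averaging.  Passing tests therefore demonstrate the
*algorithms* — conservation, determinism, oracle equality, and parameter
recovery under known geometry — not performance on real scans, where
threshold choice, rib interference and classifier quality dominate.  The
cohort correlation reproduces the direction and rough magnitude of the
published density-morphology association because the generator builds in
a monotone coupling; it validates the measurement chain, not the biology.

## Problem sizes and numerical choices

The validation suite runs phantoms at the scale the defaults describe:
vertebra-count recovery on 20-centrum volumes of 330x128x128 voxels
(165x64x64 after downsampling), one noise-free run plus twenty seeds at
SNR 5; lacuna recovery on ten 140x130x130 µm slabs of 8 lacunae; cohort
correlation at n = 40 fish.  Boundary positions are compared to truth
after removing the constant offset between the fitted axis's arc-length
origin and the generator's (the spacing pattern, not the origin, is what
the method defines).  Spline fitting uses `scipy.interpolate.splprep`
with a strictly-increasing parameterization; distance transforms and
component labeling use exact `scipy.ndimage` routines; Pearson r comes
from `scipy.stats.pearsonr`.  Degenerate inputs (constant volumes, equal
phantom grays, zero-variance cohorts, all-zero standards, coplanar
objects) raise typed errors or flagged records rather than propagating
NaNs.

## Known limitations

- The head detector assumes the head is terminal along the first
  principal axis and denser than the spine after thresholding; a head
  dimmer than bone (unusual in practice) would survive.
- Arc-length origin is defined by the fitted polyline, so absolute
  boundary positions carry an arbitrary offset; only spacings and
  positions relative to the profile are meaningful.
- The similarity statistic is amplitude-sensitive by design (matching the
  published normalization); cohorts dominated by amplitude rather than
  shape changes can score above 1.
- The radiograph coupling saturates at extreme deformation (mix cap
  0.85), where similarity stops decreasing; the default density range
  stays inside the strict regime.
- Empty vs. occupied lacunae cannot be distinguished, and canaliculi are
  out of scope.
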