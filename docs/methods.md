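# Methods

This note documents the measurement conventions, the synthetic-data model,
and the numerical choices behind `ringscale`. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Cell geometry

**Revolution volume.** The 2D cell mask is treated as the projection of a
solid of revolution about the cell's major axis. Foreground pixel-center
coordinates are rotated into the major-axis frame (continuous rotation of
coordinates; the mask is never re-rasterized, which avoids interpolation
artifacts), binned into 1-px slices along the axis, and each slice
contributes a cylinder of height 1 px whose diameter is the slice *extent*
(max − min + 1) perpendicular to the axis. The sum is converted with
`pixel_size³` to fL (1 fL = 1 µm³). Using the extent rather than the pixel
count makes the slice width well defined for solid slices; for masks with
concavities or holes inside a slice the extent over-counts — segmentation
of ovoid yeast cells does not produce such slices, but this is an
assumption, not a theorem. On rasterized spheres the estimate converges to
(4/3)πr³ (relative error < 2 % for r ≥ 30 px, < 0.5 % for r ≥ 100 px,
verified in the tests).

**Length and moment ellipses.** Cell length, ring-component orientation and
cluster axes all use the ellipse with the same normalized second central
moments as the pixel set, under the *unit-square pixel model*: each
foreground pixel contributes an additional 1/12 to the diagonal second
moments, and axis lengths are `4·sqrt(eigenvalue)`. This is the convention
of the MATLAB-style region-properties tools with which the line-profile
geometry of this kind of analysis was established (skimage's point-mass
convention differs by the 1/12 term, visible on thin objects: a 10×4 px
rectangle measures ≈ 11.55 × 4.62 px here, vs 11.49 × 4.47 px without the
correction).

**Elongation** is `(π/6)^{1/3} · L / V^{1/3}`, normalized so a sphere
scores exactly 1; for a prolate spheroid with axis ratio q it equals
`q^{2/3}`.

**Total fluorescence.** The background is the median pixel value of the
non-cell area of the 4-px-average-filtered image; the background is
subtracted from every raw in-mask pixel and the remainder summed. The
result is invariant to a constant camera offset.

**Confocal 3D reconstruction.** Per z-slice, foreground is the set of
pixels above a low threshold that are connected to pixels above a high
threshold (hysteresis). The low threshold is the Li minimum-cross-entropy
threshold, implemented as the classical fixed-point iteration
`t ← (μ_above − μ_below)/(ln μ_above − ln μ_below)` on the raw intensities
to 1e−6 absolute tolerance (ties go to the lower class; a constant slice
returns its single value). We deliberately do not use the min-shifted
variant some libraries apply: shifting by the image minimum drives the
threshold toward the background on flat-background images and inflates the
segmented area by ≈ 10 % on blurred synthetic spheroids, whereas the raw
iteration lands near the between-class point (≈ 2 % volume error on the
test ellipsoid). The high threshold is 90 % of the maximum intensity
inside the widefield 2D mask, taken over the *whole stack*: a per-slice
maximum would seed hysteresis on noise maxima in slices beyond the cell.
Volume is the voxel count × `pixel_size² · z_step`. The whole procedure is
exactly invariant under a positive gain applied to the stack (both
thresholds scale linearly).

## Ring diameter (FWHM method)

Frames are binarized at a per-dataset threshold (a required input: real
experiments calibrate it per acquisition; synthetic scenes record a
suggested value in `scene.yaml`). 8-connected components smaller than
10 px are rejected; the largest surviving component (area ties broken by
lowest label) is summarized by its moment ellipse. The brightness profile
is read along the ellipse major axis, ±30 px from the center (60 px for
large-cell strains via `half_length`), each sample being the mean of 10
bilinear samples perpendicular to the axis. A 3-sample gliding average is
applied with a shrinking window at the ends (preserving the profile length
used by the background rule); the background is the mean of the three
outermost smoothed samples on each side and is subtracted.

The diameter is the distance between the half-maximum crossings, scanning
*inward from each profile end* for the first sample at or above half the
profile maximum and refining by linear interpolation between the
bracketing samples. Scanning from the ends (rather than outward from the
center) is robust to the double-peaked profiles that edge-on rings
produce; the profile maximum is taken after background subtraction. The
sub-pixel interpolation removes a ±1 px quantization that would otherwise
bias the scaling exponent. A non-positive maximum, or a signal touching a
profile end, flags the measurement invalid (NaN) rather than raising.
Measured diameters are invariant to illumination gain and camera offset by
construction (verified as properties).

The contour-based variant (used around bud emergence) 3×3-mean-filters
each of the 5 frames, samples the profile at the cell-contour vertices,
averages the frames, takes the profile minimum as baseline, and measures
the arc length between the half-max crossings around the peak, circularly
indexed. Contours are resampled to equal arc length before profiling.

## Cdc42-GTP cluster

The per-frame threshold is the median + 2 population standard deviations
(divisor n) of in-mask intensities; cluster pixels are *strictly above*
the threshold and restricted to the cell mask (preventing bleed-through
from neighboring cells). Cluster area is the median pixel count over the
3 frames centered on peak localization (an explicit input — the original
procedure chose it by visual inspection) times `pixel_size²`. Cluster axes
are the moment-ellipse axes of the largest connected component. The
contour length variant 5×5-maximum-filters each frame (the cluster sits
slightly inside the segmentation contour), profiles 65 contour vertices,
averages the 3 frames, thresholds at the median of the three per-frame
thresholds, and reports the arc length of the contiguous suprathreshold
run containing the profile maximum.

**Local curvature** is the radius of the Kåsa algebraic least-squares
circle through the 7 contour vertices centered on the anchor (the septin
signal maximum), with the median taken over the 5 frames around bud
emergence. The algebraic fit is deterministic and exact on noiseless
circles; collinear vertices raise a degenerate-fit error, and the mean
absolute radial misfit is reported for QC. Note a known property: on a
short noisy arc (7 of 65 vertices span ≈ 33°, sagitta ≈ 0.8 px) the
algebraic fit biases a few percent low once vertex noise approaches the
sagitta; the tests pin this behavior (median within 10 % at 0.01 µm vertex
noise, bias shrinking with noise, exact at zero noise).

## Per-cell aggregation

Per-cell statistics are medians over the frames with a valid ring
detection; cells with fewer than 5 such frames are rejected (the
out-of-focus manual rejection of live experiments becomes the validity
flag plus an optional exclusion list of cell ids). Mother volume must be
supplied as the bud-free mask — a documented contract for the mask
supplier. Aging records are normalized per cell to the first division
(`d_norm = d(g)/d(1)`, `V_norm = V(g)/V(1)`); the "first bud event" is the
first generation with an accepted ring measurement. The deviation ratio of
a cell against a reference power-law fit is
`median_d / (10^intercept · median_V^slope)`.

## Scaling statistics

The power law is fitted by OLS of log10 d on log10 V; the slope is the
exponent. The 95 % CI comes from a percentile bootstrap with case
resampling of *cells* (the unit of analysis is the per-cell median), 50,000
resamples by default (tests and the acceptance script use 2,000, which
changes CI endpoints by far less than their width). Resamples with zero
volume variance (all cells identical) have no slope and are dropped;
seeded runs are exactly reproducible. Model comparison fits
`d = c·V^α` (log-space OLS), `d = a + bV` and `d = a + b·log10 V` (linear
OLS) and ranks them by SSR evaluated in diameter space for all three, so
the residuals share units; the log-space SSR of the power law is also
reported. Two-predictor regressions use statsmodels OLS with an intercept
and two-sided Wald t p-values under homoscedastic normal errors (the
classical GLM-fit convention); rank-deficient designs raise a collinearity
error. Binned means report per-bin mean x, mean y, SEM (0 by convention
for singleton bins) and n, omitting empty bins with a flag.

## Synthetic scenes

The generator emulates the study conditions, not any particular dataset:

* **Volumes** are lognormal with median 80 fL and log10 SD 0.25, spanning
  roughly 30–300 fL — the pooled range accessible with steady-state
  populations under cell-size manipulation.
* **Shape** is a prolate spheroid, aspect ratio truncated-normal ≥ 1
  (mean 1.2, SD 0.1), so volume has the closed form (4/3)πab² and
  elongation is exactly `q^{2/3}`.
* **Ring ground truth** is `d = c·V^α` times median-preserving lognormal
  noise; defaults α = 0.31, c = 0.36 µm·fL^−α (≈ 1.2 µm at 50 fL, matching
  the wild-type glycerol/ethanol regime), noise CV 0.10.
* **Rendering**: the edge-on ring is a uniform-intensity bar of length
  `d_true` across the neck (placed at 0.9·a along the major axis), 3 px
  wide, convolved with a Gaussian PSF (σ = 1 px), over a constant
  background of 100 a.u. with peak 500 a.u.; read noise is Gaussian and
  off by default so tolerance analyses are deterministic (Poisson shot
  noise is deliberately out of scope). A bar convolved with a symmetric
  kernel crosses half-maximum at the bar ends, so the analytic FWHM equals
  the bar length; the measured FWHM recovers `d_true` within ≈ 0.2 px on
  noiseless renders.
* **Pixel size** defaults to 0.1 µm/px. Absolute calibrations and
  intensity units in synthetic scenes are conventions — the measurement
  operators are gain/offset invariant, and no published pixel calibration
  is being reproduced.
* **Timecourses** place a cortical Gaussian spot (FWHM = cluster diameter,
  amplitude peaking at `cluster_peak_frame` with a 1.5-frame Gaussian
  envelope) before bud emergence, then the ring for `frame_count_ring`
  frames; the config rejects orderings where the cluster peak does not
  precede bud emergence. **Aging tracks** grow mother volume 5 % per
  generation by default and set `d_norm = V_norm^β` (default β = 0.15).
* **Randomness** flows from one seed through hierarchical `SeedSequence`
  splits (population → cell → frame): identical configs are byte-identical
  and adding cells never perturbs earlier draws.

What the renderer does *not* emulate: phase-contrast imaging, optical
aberrations beyond the Gaussian PSF, bud growth mechanics, photobleaching,
septin hourglass/double-ring substructure, or segmentation error (masks
are ground truth). Passing tests therefore demonstrate the correctness and
calibration of the *measurement and statistics* chain, not robustness to
segmentation failure modes of real phase-contrast data.

## Problem sizes and tolerances

The acceptance suite runs the full render → measure → fit pipeline on a
300-cell spherical population for the geometric-null exponent (recovered
within 0.01 of 1/3); exponent-recovery coverage uses 100 replicates of
n = 200 generator-level populations with 2,000 bootstraps each (coverage
≥ 90 % required; measured true coverage is ≈ 94 %, so the renderer's
≈ 0.5 px measurement error — far below the 10 % generator noise — is
omitted from the replicate loop); bootstrap calibration uses 500 datasets
of n = 100; the type-I error study uses 400 seeds (accepted band 3–8 % at
the 5 % level); the deviation-ratio readout renders 150 reference + 100
offset cells and requires the median ratio within 1.16 ± 0.02. The
acceptance script reports the same quantities with slightly larger sample
sizes (200 replicates; 300 + 200 cells; a 44-mother aging cohort) to
tighten the Monte-Carlo error of the reported estimates.

## Known limitations

* The FWHM crossing search direction (inward from the ends) is an
  interpretation; outward-from-center differs for multi-peak profiles.
* Slice-extent volume over-counts concave slices (see above).
* The Kåsa circle fit biases low on short noisy arcs.
* Model-comparison SSR space (diameter vs log-diameter) is a convention;
  both are computed, diameter space decides.
* The ploidy-style offset between two populations with a shared exponent
  is defined here (`log_offset_percent`) as the mean vertical offset in
  log10 diameter of one population above the other's fit, expressed in
  percent; other definitions (e.g. intercept difference at a reference
  volume) would differ slightly when the exponents are not identical.
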