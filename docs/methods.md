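# Methods

## Force spectroscopy

### Forward model

An approach force-distance curve is modelled as a flat baseline before the
contact point z0 and a Hertz-Sneddon contact force beyond it. The true
indentation is the piezo travel past contact minus the cantilever's own
deflection, delta = (z - z0) - F/k, so the force at a given piezo position
solves the implicit equation F = A(E) * delta(F)^p. The simulator solves it
exactly: for the quadratic geometries (cone, pyramid) via the
cancellation-free closed-form root (stable for arbitrarily stiff levers),
for the sphere by bracketed root finding on [0, k*(z - z0)]. The ramp is
truncated where the noiseless force first reaches the setpoint, matching
force-controlled acquisition; Gaussian force noise is added afterwards so
the curve length never depends on the noise realisation.

Units: z in um, F in nN, E in Pa, k in N/m. The single conversion constant
is 1 Pa*um^2 = 1e-3 nN.

### Contact-point initialisation

The heuristic contact estimate scans a ratio-of-variance statistic (trailing
window variance over leading window variance) across the curve; its peak
marks the noise-to-contact transition but is biased late by roughly the
force noise floor, which for soft cells corresponds to a few hundred nm of
indentation. A local refinement therefore follows: over candidate contact
samples near the scan peak, a two-segment model (constant baseline |
quadratic rise) is fitted linearly and the residual minimised. The
quadratic is the leading-order contact force for any blunt indenter, so the
refinement is geometry-agnostic. On simulated curves with 0.02 nN noise the
median error is ~0.015 um. The heuristic only initialises the joint fit; it
is never reported as a final contact point.

### Joint fit

(E, z0, baseline) are estimated by trust-region least squares on the whole
extend segment. The model prediction uses the measured force in the bending
correction, delta = (z - z0) - (F_meas - baseline)/k, which keeps the
prediction explicit (no inner root solve) and is the standard practice in
AFM batch processing; at convergence on consistent data it coincides with
the implicit model. E is parameterised on a log scale to keep the problem
well-scaled across 100 Pa - 50 kPa. Convergence tolerance is 1e-8 on the
relative parameter change with a 200-iteration budget — cheap and robust
for a 3-parameter problem. Non-convergence, no-contact and sub-minimal
post-contact support (fewer than 4 indenting samples) are reported as
`converged=False`, never as a silent modulus.

Defaults: four-sided pyramid with 35 deg half-angle (typical silicon-nitride
probe specification), Poisson ratio 0.5 (incompressible cell), spring
constant 0.03 N/m, setpoint 1 nN, approach speed 30 um/s, 15 nm z-sampling.
Only the extend segment is fitted; retract data are retained for future
adhesion analysis. Note that multiplying all forces by a constant scales
the fitted modulus by the same constant only in the pure contact model; the
bending correction breaks that scaling physically (a scaled force bends the
lever differently), so the property holds in the stiff-lever limit.

## Force-volume maps

The map fitter runs the joint fit per pixel and defines **setpoint height**
as the piezo z of the last extend sample, i.e. where the setpoint force was
reached. This is a topography proxy with one caveat worth stating: softer
material is indented further before the force target is met, so a soft cell
rim of vanishing true height still sits about delta_cell - delta_substrate
(~1 um at the defaults) above the substrate level in the setpoint-height
image.

**Segmentation** of the height image: Gaussian smoothing (sigma 0.75 px),
background estimated as a least-squares plane through the lowest-decile
pixels (substrate tilt is common in AFM maps), threshold at the plane plus
max(3 x residual MAD, 0.6 um). The 0.6 um floor sits below typical cell
heights but above both noise and half of the soft-rim height step described
above, which keeps the mask inside cell material; lower floors admit a
sub-pixel ring of substrate pixels whose ~10x stiffness would wreck the
per-cell mean. Seeds are h-maxima of depth 0.5 um (below cell height, above
noise); the watershed runs on the inverted height. Manual corrections are a
replayable edit script (merge labels / split a label from seed points /
delete a label) rather than destructive pixel painting, so a corrected
segmentation can be reproduced from the automatic one plus the script.

Per-cell statistics are plain means of E and setpoint height over the
converged pixels of each label (whole footprint, no central-region
restriction), with area = pixel count x pixel size^2. Labels without any
valid pixel are flagged and excluded downstream.

## Quantitative phase imaging

Dry-mass surface density follows m = phi * lambda / (2 pi alpha) with
lambda = 0.65 um and alpha = 0.18 um^3/pg by default. The conversion is
strictly linear and never clipped: negative phase (background noise) maps
to negative density, flagged in metadata, retained in mass sums (excluding
it would bias totals upward) and irrelevant to morphology, which uses the
label mask only. The holographic background offset is removed beforehand as
the median phase of non-cell pixels (Otsu split when no mask is supplied).

Segmentation thresholds the smoothed density at median + 5 MAD, seeds a
watershed from h-maxima, then merges adjacent regions while the maximum
density along their shared boundary (the saddle) exceeds 0.7 x the lower of
the two peak densities. The merge fraction is this package's concrete
parameterisation of "region merging": shallow internal maxima (saddle
>= 0.9 x peak) always merge, well-separated cells (saddle near background)
never do.

**Circularity** 4 pi A / P^2 uses a Crofton-style perimeter (multi-direction
intercept counts): a naive pixel-edge perimeter overestimates disk
perimeters by ~12% and biases disk circularity to ~0.89, whereas the
Crofton estimate keeps rasterised disks within 2% of 1. The estimator is
exact for random orientations but underestimates the perimeter of shapes
with long axis-aligned straight edges (an axis-aligned raster square reads
~0.88 rather than pi/4), which is immaterial for cell outlines.

## Fluorescence morphometrics

The peripheral band is the cell mask minus its erosion by a disk of the
band width (default 4 um); if erosion empties the mask the whole cell is
the band. Band and interior partition the mask exactly. Intensity
statistics are pixel sums and medians — nothing fancier, so they equal
brute-force loops exactly.

Shape metrics follow common image-analysis conventions: maximum Feret
diameter from convex-hull antipodal pairs; roundness = 4A/(pi feret^2);
aspect ratio = major/minor axis of the inertia-equivalent ellipse;
circularity as above. Fibre length is the fibre mask's maximum Feret
diameter and the fibre angle the orientation of that chord, in [0, 180)
with 0 horizontal and angles increasing counter-clockwise (image y up).

Angular dispersion is the circular standard deviation sqrt(-2 ln Rbar).
`raw` mode applies it to the angles as given (period 360 deg), matching the
direct use of a circular-std routine on Feret angles; `axial` mode doubles
the angles first and halves the result, the statistically correct treatment
for orientations whose period is 180 deg (a 170 deg fibre is 20 deg from a
10 deg fibre). Raw is the default for comparability; axial is recommended
for fibre data.

## Assays

**Colony forming.** Rigid registration maximises the translation-aligned
grayscale correlation over rotation (coarse 1 deg grid within +/-10 deg,
then bounded scalar refinement to 0.01 deg; translation per candidate from
upsampled phase correlation). An aligned correlation below 0.2 raises a
registration failure. The reference ROI is resampled onto the moving image
through the inverse transform. Colonies are pixels whose CIELAB b channel
(D65, sRGB input) falls below a single fixed threshold, default -35: the
midpoint between plate (~+3) and saturated stain (~-74), which puts the
decision boundary at the half-coverage contour of an anti-aliased colony
edge and keeps area fractions unbiased. The alternative reading of "blue
component" as a blueness score rather than the b channel is noted; the b
channel is implemented.

**Impedance (RTCA).** CI(t) = (Z(t) - Z_blank(t))/Z_nominal per time point;
normalisation divides by CI at the treatment time, interpolated linearly
when it falls between samples (15-min sampling makes the interpolation
numerically minor). Relative invasiveness is the normalised CI of a
Matrigel-coated well. The pipeline is invariant to rescaling all impedances
and the nominal jointly.

**Migration.** Per-cell speed is path length over elapsed time. The rose
histogram has 12 bins of 30 deg, the first centred on +x, weighted by step
speed so fast steps dominate (a speed rose; pure step counting is the
obvious variant and the weights reduce to counts for uniform speeds). The
summary vector is the vector sum of all displacement steps divided by the
total path length of all cells — magnitude 1 for straight common motion, 0
for balanced motion, <= 1 always by the triangle inequality. A
per-cell-then-average variant is exposed as an option.

**Wound healing.** Open-area percentages are accepted as input from
external wound software; the module only forms per-well closures
(open_t0 - open_t24) and flags negative closures (widening).

## Statistics dispatch

Each group is tested with Shapiro-Wilk at alpha = 0.05 (a standard choice
where the normality check is otherwise unspecified). All groups normal ->
ANOVA (repeated-measures via statsmodels when a pairing structure exists,
one-way otherwise); any group non-normal or constant -> Kruskal-Wallis.
The chosen branch and the per-group normality p-values are returned, making
the decision audit-reproducible. With three groups the all-normal gate
passes ~86% of truly normal datasets (three 5% gates compound), and the
dispatched procedure holds its level: the measured type-I error over 2000
null replicates at n = 30/group is ~0.05. Correlations dispatch the same
way into Pearson/Spearman. No multiple-testing correction is applied by
default (mirroring common practice in this literature); a Holm option
exists on the caller's side via the returned p-values.

Comparative Ct: dCt = Ct_target - Ct_ref, ddCt = dCt - dCt_calibrator,
relative expression 2^-ddCt; invariant to shifting all reference Ct values
by a constant.

## Synthetic data

Each generator draws from a named substream of the master seed
(`default_rng([seed, stream_id])`), so generators are individually
reproducible and mutually independent. What they emulate, and what they do
not:

- **Force maps**: cos^2-profile cells (3 um tall, 8 um radius, default two
  cells at 700/1200 Pa) on a 10 kPa substrate, 32 x 32 pixels over
  40 x 40 um by default (a desk-scale stand-in for 64 x 64 vendor maps —
  the shape is a parameter), each pixel a full forward-model curve with
  0.02 nN noise. The cell-stiffness region extends 3 um beyond the
  topographic footprint: a real cell's thin rim still covers the substrate,
  so an indenting tip meets cell material where the height signal has
  vanished. Without this rim the stiffness field would step 10x exactly at
  a zero-height boundary — a configuration no segmentation can trace at
  pixel resolution and one that does not occur physically. Not emulated:
  viscoelastic response, adhesion on retract, substrate bottom-effect
  stiffening.
- **Phase images**: cos^2 mass profiles scaled so the rasterised total
  equals the requested dry mass exactly, inverted to phase, plus a 0.2 rad
  background offset and 0.01 rad noise. Not emulated: halo/shade-off
  artefacts, phase wrapping.
- **Fibre images**: straight segments with Gaussian cross-section, angles
  von Mises(mu, kappa); the truth records the drawn angles and their
  circular dispersion. Not emulated: fibre curvature, crossings resolved in
  intensity.
- **Colony plates**: non-overlapping anti-aliased blue disks on a white
  plate until the target ROI fraction (default 0.30) is met; truth is the
  exact rasterised fraction. Not emulated: uneven illumination, stain
  gradients.
- **Tracks**: biased persistent random walks (heading diffusion plus a
  drift mixing weight; bias 1 is exactly straight).
- **Impedance**: logistic CI growth (plateau 8, rate 0.08/h) sampled every
  15 min for 150 h (601 points), treatment at 48 h as a growth-rate
  multiplier, inverted to impedance exactly through the CI definition.

Because the generators realise the same forward models the analysis
inverts, passing round-trip tests demonstrates correctness of the
implementation and internal consistency of the pipelines — not performance
on real microscope data, with its uncorrected artefacts, debris and
segmentation ambiguity. Real-data workflows should expect to tune the
segmentation thresholds (`min_offset`, `h_depth`, merge fraction, Lab
threshold) to their instruments.

## Problem sizes and determinism

Default problem sizes (32 x 32 force maps, 192 x 192 phase images,
256 x 256 plates, 100 tracks, 2000 statistical replicates) keep the full
test suite and the acceptance script in the tens of seconds on one CPU
while leaving every estimate's sampling error far inside its tolerance.
All stochastic paths take either an integer seed or a Generator; fixed
seeds reproduce outputs bit for bit.

## Known limitations

- The Hertz fit assumes a linear-elastic half-space: no correction for
  finite cell thickness (bottom effect), no viscoelasticity, and the
  approach speed enters only as metadata.
- Registration covers rigid transforms only (translation + rotation up to
  +/-10 deg by default); scale and shear are out of scope.
- The QPI module does not unwrap phase; inputs are assumed unwrapped by the
  instrument software.
- Automatic stress-fibre detection is deliberately absent — fibre masks are
  manual or imported, as is standard for these measurements.
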