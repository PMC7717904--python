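# Methods

`hcrquant` re-implements, as a tested library, the image-quantification
chain used to measure gene expression in whole-mount HCR-stained mouse
embryos: flat-field shading correction, per-probe baseline subtraction,
a marker-defined volumetric tissue model, masked intensity density,
ellipsoidal spot models with fixed intensity bins, oscillation-phase
classification of striped presomitic-mesoderm (PSM) expression, and
cohort statistics.  Because no raw imaging data are publicly deposited
for this kind of experiment, validation is built on a synthetic
embryo-phantom generator with exact ground truth; every number the
package reports is recomputed at run time from freshly generated
phantoms.

## Axis and unit conventions

Arrays are ordered `(z, y, x)` = (dorsoventral, mediolateral,
anteroposterior), anterior at `x = 0` ("anterior left").  All physical
parameters are in µm; intensities are arbitrary units (a.u.).  Default
voxel spacing is (2.5, 0.9, 0.9) µm — the xy pitch of a 10× confocal
acquisition; the z-step is an assumption chosen to keep a full stack
near 10⁷ voxels, since whole-mount acquisitions rarely sample z finer
than a few µm at this magnification.

## The synthetic embryo phantom

The generator (`hcrquant.synthetic`) emulates a 5–6-somite-stage tail
region:

* **Reference domain** (*Tbx6*-like): two bilateral AP-oriented bands
  (90 µm wide) flanking a 100 µm midline gap, 600 µm long and 80 µm
  thick, merging across the midline in the posterior quarter (the
  tailbud).  The analytic volume is 9.84 × 10⁶ µm³, inside the
  [9.0 × 10⁶, 1.1 × 10⁷] µm³ window used for mask-volume targeting.
  Edges are softened over 2 µm; the hard geometric mask is the ground
  truth.
* **Target channel** (*Hes7*-like): 2–3 transverse stripes, each a
  separable anisotropic Gaussian bump (concentric intensity gradient,
  peak 2000 a.u., AP FWHM 60 µm) over a pan-domain floor of 150 a.u.,
  plus off-target expression in a neural-ectoderm-like midline slab
  outside the reference domain.  Stripe layouts encode the three
  oscillation phases: phase I — three stripes with the anterior one
  touching the anterior boundary and the posterior one confined to the
  posterior midline (ML FWHM 70 µm vs 238 µm for a full stripe);
  phase II — two laterally expanded stripes clear of the anterior
  boundary; phase III — two full stripes plus a low-amplitude (30% of
  peak) stripe initiating at the posterior midline.  Total stripe flux
  is renormalized to a phase-independent constant, reflecting that the
  oscillation redistributes rather than creates transcript; without
  this, cohort expression estimates would depend on the random phase at
  fixation.  Per-embryo variability: stripe centers jitter by 5 µm
  (s.d.), widths by 3% CV, and overall stripe amplitude by 3% CV —
  chosen so that cohorts at the study's sample sizes (n = 6–11) resolve
  the genotype effect sizes the pipeline is asked to recover.
* **Genotype effects** scale the target channel (and punctum
  intensities) multiplicatively: control 1.0, plus factors 0.518, 0.81,
  0.67 and 0.20 for the mutant cohorts the package models.  Factor 0
  denotes a probe-null specimen used for baseline calibration.
* **Punctate channel** (intron-probe-like): ~3 × 10⁻⁵ puncta/µm³
  placed inside the domain with 80% of positions drawn proportional to
  the stripe field (nascent transcription concentrates in stripes) and
  a minimum anisotropy-scaled separation of 8 µm.  Each punctum is a
  σ = (1.4, 0.7, 0.7) µm Gaussian blob whose discrete voxel sum equals
  its drawn intensity.  Intensities follow a piecewise-uniform mixture
  over the five fixed bins (1000–6000–11000–16000–21000–26000 a.u.)
  with weights 40 : 30 : 20 : 10 : 0.5 — the calibrated control
  distribution.  Punctum intensities are specified in *measured*
  (shading-corrected) units: rendered emission is boosted by the
  reciprocal mean vignette gain (computed from the spec) and by a
  1.09 aperture/clamping factor, so that the measurement chain returns
  the drawn values on average.
* **Acquisition model**: a radial multiplicative vignette
  `gain(d) = g_min + (1 − g_min)·exp(−(d/falloff)²)` with g_min = 0.7
  and falloff 400 µm; Poisson shot noise at 0.5 photons/a.u.; Gaussian
  read noise (s.d. 2 a.u.); constant detector baseline of 10 a.u.
  Shot noise is sampled exactly below 25 expected photons and by its
  Gaussian limit above, where the approximation error is far below
  read noise.  Flat-field stacks are the vignette sampled with 0.5%
  dye noise.  All randomness derives from the spec seed; identical
  specs give bit-identical stacks.

What the phantom does **not** model: optical PSF blur beyond the
axial elongation of spots, scattering and depth-dependent attenuation,
per-cell texture, segmentation of formed somites, or registration
across embryos.  Passing tests therefore demonstrate correctness of the
measurement chain under a controlled forward model, not robustness to
every artifact of real clearing and confocal imaging.

## Calibration

Shading correction divides by the flat field normalized to its mean
(`out = in × mean(ff)/ff`), which preserves the mean of a uniform
specimen up to O(var(gain)).  The baseline cutoff for a probe is the
smallest value `c` such that at most a `tolerance` fraction (default
10⁻⁴) of voxels in a negative reference — a non-expressing tissue
region, or the whole stack of a probe-null specimen — exceed `c`;
it is computed exactly from the pooled order statistics, and
subtraction is clamp-at-zero (`max(v − c, 0)`), preserving relative
differences above baseline rather than discarding sub-cutoff voxels.
Because the cutoff must clear the noise ceiling of the corrected
baseline everywhere, a small constant per-voxel signal loss survives;
it depresses recovered expression ratios by well under one percentage
point at the default signal levels and is visible in the residual bias
of the cohort recoveries.

## Volumetric masking and intensity density

The reference channel is smoothed with a Gaussian whose FWHM equals the
3 µm surface-detail scale (in physical units, so anisotropic in
voxels) and thresholded at an absolute intensity.  Mask volume is
monotone non-increasing in the threshold, so the volume-targeted search
is an exact order statistic: the threshold retaining just enough voxels
to reach the window's lower bound — the largest (most conservative)
qualifying threshold, found without iteration; ties and
component-filtering effects fall back to an exhaustive scan of the
achievable volumes.  Connected components below 1000 µm³ are dropped
(speckle) while keeping the bilateral bands; the window is applied to
the summed bilateral volume.  Expression is reported as intensity sum
within the mask over mask volume (a.u./µm³).  Manual-annotation masks
interpolate polygon ROIs between annotated z-planes by linear blending
of signed-distance transforms, the standard reconstruction for
alternating-plane annotation.

## Spot models

Puncta are detected by anisotropic Laplacian-of-Gaussian filtering at
lateral scale `diameter/2√3` and axial scale `psf_axial/2√3` (defaults
4 and 8 µm for diameter and axial extent), local maxima above a robust
(MAD-based) noise floor at 6 σ, and brightness-ranked de-duplication
within one spot radius.  Sum intensity integrates the channel over the
4 × 8 µm ellipsoid; with local background on, the median of a
1.0–1.5-radius shell times the ellipsoid voxel count is subtracted,
which cancels any locally constant offset.  Bins are half-open
[lo, hi): low 1000–6000, low-medium 6000–11000, medium 11000–16000,
medium-high 16000–21000, high ≥ 21000 a.u.; ties go to the upper bin;
spots under 1000 a.u. are excluded from distribution percentages.  The
1500 a.u. sum-intensity threshold is applied by `filter_spots` where an
analysis calls for it; bin-distribution analyses default to binning
without the pre-filter, since the lowest bin starts below the filter
threshold.  Heat-map values are the linear ramp of sum intensity over a
configured [min, max] scale, clamped to [0, 1].

## Oscillation-phase classification

The AP profile is the mean masked intensity in 5 µm bins, smoothed by
10 µm, and padded with its minimum so stripes truncated at the mask
boundary keep their full prominence.  Peaks separated by ≥ 40 µm are
stripes: *full* if prominence ≥ 20% of the profile range, *initiating*
if prominence is in [5%, 20%) at the posterior 15% of the mask and
midline-limited.  ML extent is the half-peak-height span of the z-MIP
restricted to the stripe's AP window, as a fraction of the mask's ML
span there; "midline-limited" means ≤ 0.4, and a stripe "reaches the
anterior boundary" if its half-height edge comes within 5% of the mask
AP length.  Rules, in order: three full stripes with a midline-limited
posterior stripe and a boundary-reaching anterior stripe → I; two full
stripes plus an initiating posterior-midline stripe → III; two full
stripes with a laterally expanded posterior stripe and an anterior
stripe short of the boundary → II; otherwise unclassifiable.  All
thresholds are config-exposed (`StripeDetectParams`); the defaults were
fixed against noise-free phantoms.  The trough metric is the profile
minimum between the two most prominent adjacent peaks over their mean
height — 1 means no trough (failed repression), 0 a complete one.

## Cohort statistics

Group summaries are mean ± s.e.m. (unbiased s.d. / √n).  The genotype
comparison is the classical pooled-variance two-tailed Student t-test
(df = n₁ + n₂ − 2); Welch's correction is deliberately not the default
because the procedure modeled names the Student test, and group
variances are comparable by construction.  Degenerate zero-variance
inputs follow an explicit contract (equal means → t = 0, p = 1;
unequal → p = 0, flagged).  Expression ratios are ratios of group
means (scale-invariant), reported as percent of control.  Per-bin spot
comparisons are uncorrected per-bin t-tests; a multiple-testing
correction is out of scope by design.  Type-I calibration and
bias checks of the ratio estimator run at summary level (per-embryo
densities drawn from a normal with constant CV), which isolates the
statistics from the imaging chain.

## Problem sizes and determinism

Default phantoms are 48 × 360 × 720 voxels (≈ 1.2 × 10⁷).  The
end-to-end validation suite uses the paper-scale cohorts (8–20 embryos)
at full resolution for the expression-ratio recoveries and a coarse
(24 × 180 × 360) variant of the same physical phantom for the
phase-classification studies, where stripes are hundreds of µm wide
and the finer pitch adds nothing.  Every stochastic step flows from a
single integer seed through `numpy` `SeedSequence` spawning; repeated
runs are bit-identical.

## Known limitations

* The shading-correction normalization convention (mean of the flat
  field) sets the absolute intensity scale; analyses tied to absolute
  bin edges assume data calibrated under the same convention.
* Baseline subtraction introduces a small genotype-ratio bias
  (≤ ~1 percentage point at default settings) because the calibrated
  cutoff sits a few noise s.d. above the corrected baseline.
* Mutant-phase classification is not validated — the phantom's mutant
  patterns are idealized, whereas real mutant expression is described
  as disordered precisely where classification is hardest.
* Spot sum intensities carry a ~5–9% aperture/discretization loss;
  distribution analyses are calibrated for it, absolute single-spot
  photometry is not the goal.
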