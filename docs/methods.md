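# Methods

## The measurement model

punctakit treats a fluorescent nerve cord as a one-dimensional object: all
reported quantities (punctum width in µm along the cord, density per 10 µm,
peak intensity) are defined on the linescan, the intensity profile sampled
along a user-drawn path on a maximum-intensity projection. Thresholding
therefore also runs on the 1D profile rather than the 2D image; a 2D
detection mode is deliberately out of scope. This keeps every step exactly
reproducible and makes the position↔pixel accounting trivial.

Conventions: 0-based pixel coordinates with positions at pixel centers,
`(x, y)` vertex order matching ImageJ, arc length in µm from the first path
vertex. The path is resampled at exactly 1 pixel of arc length; at each
sample the intensity is the mean of `line_width_px` (default 3) bilinear
interpolations spaced 1 px apart along the local perpendicular. The mean
(not max) suppresses single-pixel noise and matches common linescan
practice; bilinear interpolation is documented so oracle tests can be
exact. Spatial calibration precedence is: explicit config override → sample
sheet column → TIFF resolution tags; a missing calibration is a hard error,
never a silent default. A `(1, 1)` XResolution rational is treated as the
writers' placeholder, i.e. no calibration.

## Detection

1. **Smoothing** — Gaussian, σ = 0.5 px, reflect boundaries; σ = 0 is the
   identity. The same smoothed profile is used for thresholding *and* for
   measurement, so the detected segment and the measured peak always refer
   to the same signal.
2. **Phansalkar local adaptive threshold** — intensities are min–max
   rescaled to [0, 1]; over a window of ±`radius_px` (default 2, reflected
   at the ends) with mean *m* and *population* standard deviation *s*
   (divisor = window size, matching common auto-local-threshold
   implementations), the threshold is
   `t = m·(1 + p·e^(−q·m) + k·(s/r − 1))` with defaults k = 0.25, r = 0.5,
   p = 2, q = 10 — the method's published constants, all overridable.
   Foreground is *strict* inequality (rescaled intensity > t); ties are
   background, which makes a perfectly flat profile yield an all-false mask
   (with a warning, not an error). The min–max rescale makes the mask
   invariant to affine intensity transforms aI + b (a > 0).
   One numerical guard: the sliding-window mean is clamped at 0, because
   the uniform filter can return means of about −10⁻¹⁸ on all-zero
   background plateaus, which would make t negative and flag flat
   background as foreground.
3. **Size filter** — maximal supra-threshold runs shorter than
   `min_size_px` (default 10) are discarded. The protocol's "size = 10" is
   unitless; pixels are used because radius and sigma are also
   pixel-denominated (a µm option would require the calibration and is not
   the default).

## Measurement

- **Peak**: maximum smoothed intensity in the segment, earliest index on
  ties (deterministic).
- **Baseline** for "half-maximal": the median intensity of all
  sub-threshold samples of the smoothed profile — a robust global floor.
  An alternative `local_edges` mode (the lower of the two samples flanking
  the segment) is available via `baseline_method`; the resolved choice is
  echoed with every run's configuration.
- **FWHM**: half level = baseline + (peak − baseline)/2; walk left and
  right from the peak to the first sample strictly below the half level
  and interpolate each crossing linearly between the straddling samples.
  If either walk leaves the profile, the width is undefined and the
  punctum is flagged `at_edge`.
- **Edge policy**: edge-flagged puncta (truncated by the profile ends, or
  with undefined width) are *counted* for density — their existence is
  real — but *excluded* from the per-animal intensity and width means —
  their measurements are not. Zero-puncta animals propagate missing means
  (never zeros) into the group statistics.
- **peak-to-bead**: peak / bead intensity, dimensionless; one scalar bead
  value per session is supplied in the sample sheet, cancelling arc-lamp
  drift between sessions. The smoothed peak is used, consistent with
  detection.

## Group statistics

Animals, not puncta, are the statistical units: tests run on per-animal
means and densities. Shapiro–Wilk p-values are reported as a normality
gate but never switch the test — the workflow always proceeds to the
two-sample Kolmogorov–Smirnov test. The KS p-value is exact when
n₁·n₂ ≤ 10⁴ (typical per-animal group sizes, e.g. 13 × 28 = 364, sit well
inside this regime) and asymptotic above; the mode used is recorded in the
output. Effect sizes are percent change of the mutant mean relative to the
wild-type mean; intensity plots can be normalized to the wild-type mean
(which then equals 1 exactly). The three metrics are reported without
multiple-testing correction, matching the fixed three-readout protocol; a
Bonferroni-adjusted column is emitted for transparency but not used for
calls. The exact KS statistic is discrete, so the null rejection rate at
α = 0.05 is slightly conservative (≈ 0.043 at 13 vs 28 over 2000
replicates; the `calibrate-null` subcommand recomputes this).

## Synthetic data: what it emulates and what it does not

The generator plants puncta along straight synthetic cords by a Poisson
process at a planted rate, each a Gaussian bump (so FWHM ground truth is
closed-form, FWHM = 2√(2 ln 2)·σ ≈ 2.3548σ; Lorentzian and boxcar shapes
are available for robustness checks), on a constant background with
additive Gaussian detector noise (Poisson shot noise behind a flag). The
defaults are the study conditions the package targets: 13 wild-type-like
vs 28 mutant-like animals, 100 µm of analyzed cord at 0.108 µm/px, puncta
of FWHM 2.0 ± 0.2 µm and amplitude 100 ± 10 over background 20, density
1.5 per 10 µm, bead intensity 200, per-pixel noise sd 20 (amplitude/noise
= 5), and a mutant contrast of ×1.5 width, ×1.4 amplitude, ×0.6 density —
the wider/brighter/sparser phenotype direction of *daf-7*-like mutants.

`noise_sd` is defined as *per-pixel camera* noise. A directly emitted 1D
profile stands for a linescan averaged over `linescan_width_px` (default
3) perpendicular pixels, so its additive noise is `noise_sd/√3`; this
keeps the profile and 2D-image render modes statistically consistent —
the image route always passes through the width-3 perpendicular mean in
`extract_profile`.

An optional `min_separation_um` draws positions from the uniform
distribution conditioned on all gaps ≥ s (sampled exactly via sorted
uniforms on the shrunken interval), used by the recovery benchmarks at
5 µm ≈ 2.5× the planted FWHM: exact-count and ±0.15 density recovery are
only meaningful claims for resolvable puncta, since the detector
deliberately performs no peak splitting of merged puncta. The default
study keeps unconstrained Poisson placement, so occasional merges are part
of the end-to-end conditions.

What passing these tests does **not** show about real data: the generator
has no point-spread function, no cord curvature or varying cord thickness,
no background structure (gut autofluorescence, coverslip debris), no
photobleaching within a session, and Gaussian-shaped puncta only. Results
on real micrographs depend on those factors and on the quality of the
drawn cord path.

## Numerical choices and degenerate inputs

- Sliding-window mean/variance via uniform filters; window mean clamped at
  ≥ 0 (see above); `ndimage` reflect (symmetric) boundary convention
  throughout, matching `np.pad(mode="symmetric")` in the oracles.
- Tie-breaks: earliest index for peak plateaus; strict inequality for
  foreground.
- Flat profile → empty detection with a warning; all-foreground mask →
  error (no background to estimate); peak ≤ baseline → undefined width,
  punctum excluded from means; zero wild-type mean → normalization error.
- Determinism: every stochastic component (generator, null calibration)
  flows from explicit integer seeds through `numpy.random.default_rng`;
  per-animal streams are derived from the study seed and animal index, so
  identical (spec, seed) reproduce outputs bit-for-bit.
- Benchmark sizes (100-punctum recovery runs, 50-animal density checks,
  2000 null replicates) were chosen so the whole validation suite runs in
  seconds while keeping Monte-Carlo error well below the asserted bands.

## Known limitations

- No watershed/peak splitting: two puncta closer than roughly the
  threshold cut width (~1.5× FWHM) merge into one detection, biasing
  density down and width up at high densities — visible in the default
  end-to-end study and accounted for in its direction-only claims.
- Peak height is taken as a maximum over noisy samples and is therefore
  biased slightly upward under noise, which biases FWHM slightly downward
  (≈ 7% at amplitude/noise = 5); width *comparisons* between groups are
  unaffected because the bias is common to both.
- The ImageJ `.roi` reader supports polyline-family ROIs (int16 and
  subpixel coordinates), not the full ROI zoo.
- Per-punctum integrated intensity, colocalization, kymographs and cord
  auto-tracing are out of scope; the cord path is user-supplied.
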