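# punctakit

Quantification of fluorescent puncta along neurite linescans.

Tagged synaptic proteins — GLR-1::GFP in the *C. elegans* ventral nerve
cord is the motivating case — accumulate in discrete puncta whose
intensity, width and spacing report on receptor trafficking. punctakit is
an open, scriptable implementation of the standard measurement protocol
for such images: extract a 1D intensity profile (linescan) along a
user-drawn cord path, detect puncta on it, measure each one, aggregate per
animal, and compare genotype groups.

## Method

Given a maximum-intensity projection with spatial calibration (µm/pixel)
and a cord path, the profile *I(x)* is sampled at 1-pixel arc-length steps
(mean of a 3-pixel-wide perpendicular band, bilinear interpolation). The
detection chain is:

1. **Gaussian smoothing**, σ = 0.5 px.
2. **Phansalkar local adaptive thresholding** on min–max-rescaled
   intensities: with window mean *m* and population standard deviation *s*
   over a ±2-pixel window,

   *t = m · (1 + p·e^(−q·m) + k·(s/r − 1))*,  k = 0.25, r = 0.5, p = 2, q = 10,

   and a sample is foreground iff its rescaled intensity exceeds *t*. The
   *p·e^(−q·m)* term raises the threshold in dim regions, which is what
   lets this method find puncta that global thresholds miss.
3. **Size filtering**: supra-threshold runs shorter than 10 px are
   discarded.

Each punctum is then measured on the smoothed profile:

- **peak-to-bead** — peak intensity divided by the intensity of a standard
  fluorescent calibration bead imaged in the same session (cancels
  illumination drift);
- **FWHM** — full width at half maximum in µm, with the half level
  referenced to the median sub-threshold intensity and crossings linearly
  interpolated;
- **density per 10 µm** — 10 · n<sub>puncta</sub> / cord length.

Per-animal means feed the group statistics: a Shapiro–Wilk normality check
(reported, not used to switch tests) followed by a two-sample
Kolmogorov–Smirnov test on per-animal values, with effect sizes as percent
change of the mutant mean versus the wild-type mean.

Because no public micrograph set exists for this protocol, the package
ships a synthetic-data generator (`punctakit.simulate`) that plants
Gaussian puncta with known position, amplitude and FWHM along noisy
synthetic cords — every stage is validated against this ground truth.

## Worked example

```sh
punctakit simulate --out study/ --seed 1           # 13 "wt" + 28 "mut" animals
punctakit analyze --sample-sheet study/sample_sheet.csv --out results/
punctakit compare --animals results/per_animal.csv --out comparison/
```

The last command prints (for the default planted contrast — mutant puncta
1.5× wider, 1.4× brighter, 0.6× as dense):

```
mean_peak_to_bead: +26.3% (KS D=0.852, p=5.18e-07, exact)
mean_fwhm_um: +58.3% (KS D=0.964, p=1.59e-09, exact)
density_per_10um: -47.2% (KS D=0.964, p=1.59e-09, exact)
```

i.e. the mutant-like group shows brighter and wider puncta at lower
density, each difference significant by the exact two-sample KS test on
per-animal values (13 vs 28 animals). `comparison/` also receives a CSV,
a JSON report, a swarm + mean±SEM figure, and the fully-resolved
configuration used.

The same workflow is available from Python — see `examples/`
(`single_animal.py`, `full_study.py`, `image_linescan.py`). Real data
enters through a sample sheet CSV (`file, animal_id, genotype,
bead_intensity, cord_path_file, um_per_px`) pointing at grayscale TIFFs
(Z-stacks are max-projected; calibration read from resolution tags unless
overridden) with ImageJ `.roi` polylines or `x,y` CSVs as cord paths.

All detection parameters (`--sigma --radius --min-size --k --r --p --q`)
and pipeline options are settable via CLI flags or a YAML config;
`punctakit calibrate-null` checks the empirical type-I error of the KS
test at your group sizes.

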