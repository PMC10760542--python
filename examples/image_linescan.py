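"""Extract a linescan from a 2D cord image and detect puncta on it.

Renders a synthetic 2D micrograph (straight cord with Gaussian transverse
profile plus detector noise), samples the intensity along the cord path with
a 3-pixel-wide linescan, and runs detection on the resulting 1D profile —
the same route a real calibrated TIFF plus ImageJ polyline ROI would take.
"""

from punctakit import SyntheticSpec, analyze_profile, extract_profile, generate_animal

spec = SyntheticSpec(min_separation_um=5.0)
image, cord_path, truth = generate_animal(spec, "mut", seed=3, render="image")
profile = extract_profile(image, cord_path)
record = analyze_profile(profile, spec.bead_intensity)

print(f"image {image.pixels.shape} at {image.um_per_px} um/px, "
      f"cord length {profile.span_um:.1f} um")
print(f"planted {truth.n_puncta} puncta, detected {len(record.puncta)}")
print(f"mean FWHM {record.mean_fwhm_um:.2f} um "
      f"(planted mean {truth.fwhm_um.mean():.2f} um)")
print(f"mean peak-to-bead {record.mean_peak_to_bead:.2f}, "
      f"density {record.density_per_10um:.2f} per 10 um")
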