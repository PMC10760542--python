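"""Per-punctum measurement and per-animal aggregation.

A punctum is measured on the smoothed profile: its peak (maximum intensity
within the segment, earliest index on ties), its peak-to-bead ratio (peak
divided by the session's calibration-bead intensity, a dimensionless number
that cancels illumination drift), and its full width at half maximum. The
half-maximum level is referenced to a baseline, taken by default as the
median of all sub-threshold samples of the profile — a robust global floor.

Edge policy: a punctum whose half-maximum crossings cannot both be found
inside the profile (or whose segment touches a profile end) is flagged
``at_edge``; it still counts toward density (its existence is real) but is
excluded from per-animal intensity/width means (its measurements are not).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from punctakit.detection import Segment
from punctakit.image_io import IntensityProfile

__all__ = [
    "Punctum",
    "AnimalRecord",
    "measure_peak",
    "estimate_baseline",
    "fwhm",
    "peak_to_bead",
    "density_per_10um",
    "measure_puncta",
    "aggregate_animal",
]


@dataclass(frozen=True)
class Punctum:
    """One detected punctum with its measurements.

    ``fwhm_um`` is ``None`` when a half-maximum crossing falls outside the
    profile; such puncta are flagged ``at_edge``.
    """

    segment: Segment
    peak_pos_um: float
    peak_intensity: float
    baseline: float
    peak_to_bead: float
    fwhm_um: float | None
    at_edge: bool


@dataclass(frozen=True)
class AnimalRecord:
    """Per-animal aggregate of puncta measurements.

    Means are over non-edge puncta with defined FWHM; density counts all
    detected puncta over the full analyzed span. Means are NaN (missing),
    never zero, when no punctum qualifies.
    """

    animal_id: str
    genotype: str
    bead_intensity: float
    puncta: list[Punctum]
    cord_length_um: float
    mean_peak_to_bead: float
    mean_fwhm_um: float
    density_per_10um: float


def measure_peak(profile: IntensityProfile, segment: Segment) -> tuple[float, float]:
    """Peak position (um) and intensity within a segment; ties -> earliest."""
    if segment.end_idx >= len(profile):
        raise ValueError("segment extends beyond profile")
    window = profile.intensities[segment.start_idx : segment.end_idx + 1]
    offset = int(np.argmax(window))  # argmax returns the first maximum
    idx = segment.start_idx + offset
    return float(profile.positions[idx]), float(window[offset])


def estimate_baseline(profile: IntensityProfile, mask: np.ndarray) -> float:
    """Median intensity of sub-threshold (mask False) samples."""
    mask = np.asarray(mask, dtype=bool)
    background = profile.intensities[~mask]
    if background.size == 0:
        raise ValueError("no background available: mask is all foreground")
    return float(np.median(background))


def fwhm(
    profile: IntensityProfile,
    peak_pos_um: float,
    peak_intensity: float,
    baseline: float,
) -> float | None:
    """Full width at half maximum of a peak, in microns.

    The half level is ``baseline + (peak - baseline) / 2``. From the peak
    sample, walk outward to the first sample strictly below the half level
    on each side and linearly interpolate each crossing between the
    straddling samples. Returns ``None`` if either walk runs off the profile
    before crossing (edge-truncated peak).
    """
    if peak_intensity <= baseline:
        raise ValueError("non-positive prominence: peak <= baseline")
    pos = profile.positions
    intens = profile.intensities
    half = baseline + (peak_intensity - baseline) / 2.0
    peak_idx = int(np.argmin(np.abs(pos - peak_pos_um)))

    def _crossing(direction: int) -> float | None:
        i = peak_idx
        while 0 <= i + direction < len(intens):
            j = i + direction
            if intens[j] < half:
                # interpolate between samples i (>= half) and j (< half)
                frac = (intens[i] - half) / (intens[i] - intens[j])
                return float(pos[i] + frac * (pos[j] - pos[i]))
            i = j
        return None

    left = _crossing(-1)
    right = _crossing(+1)
    if left is None or right is None:
        return None
    return right - left


def peak_to_bead(peak_intensity: float, bead_intensity: float) -> float:
    """Ratio of punctum peak intensity to calibration-bead intensity."""
    if not (bead_intensity > 0):
        raise ValueError("invalid bead calibration: bead intensity must be > 0")
    return peak_intensity / bead_intensity


def density_per_10um(n_puncta: int, cord_length_um: float) -> float:
    """Puncta per 10 microns of analyzed cord."""
    if not (cord_length_um > 0):
        raise ValueError("cord length must be > 0")
    return 10.0 * n_puncta / cord_length_um


def measure_puncta(
    profile: IntensityProfile,
    mask: np.ndarray,
    segments: list[Segment],
    bead_intensity: float,
    baseline_method: str = "global_median",
) -> list[Punctum]:
    """Measure every detected segment on the (smoothed) profile.

    ``baseline_method="global_median"`` (default) shares one baseline across
    puncta: the median of sub-threshold samples. ``"local_edges"`` uses, per
    punctum, the lower of the two profile values flanking its segment. A
    segment whose peak does not rise above its baseline — possible for
    spurious detections on noise — gets an undefined FWHM and is edge-flagged
    so it never enters the means.
    """
    if baseline_method not in ("global_median", "local_edges"):
        raise ValueError(f"unknown baseline method {baseline_method!r}")
    global_baseline = estimate_baseline(profile, mask)
    n = len(profile)
    puncta = []
    for seg in segments:
        peak_pos, peak_int = measure_peak(profile, seg)
        touches_end = seg.start_idx == 0 or seg.end_idx == n - 1
        if baseline_method == "local_edges":
            lo = profile.intensities[max(seg.start_idx - 1, 0)]
            hi = profile.intensities[min(seg.end_idx + 1, n - 1)]
            baseline = float(min(lo, hi))
        else:
            baseline = global_baseline
        if peak_int > baseline:
            width = fwhm(profile, peak_pos, peak_int, baseline)
        else:
            width = None
        puncta.append(
            Punctum(
                segment=seg,
                peak_pos_um=peak_pos,
                peak_intensity=peak_int,
                baseline=baseline,
                peak_to_bead=peak_to_bead(peak_int, bead_intensity),
                fwhm_um=width,
                at_edge=touches_end or width is None,
            )
        )
    return puncta


def aggregate_animal(
    profile: IntensityProfile,
    puncta: list[Punctum],
    bead_intensity: float,
    animal_id: str = "",
    genotype: str = "",
) -> AnimalRecord:
    """Aggregate puncta into a per-animal record.

    Density uses all detected puncta over the full profile span; the
    intensity and width means use only non-edge puncta with defined FWHM.
    """
    if not (bead_intensity > 0):
        raise ValueError("invalid bead calibration: bead intensity must be > 0")
    span = profile.span_um
    included = [p for p in puncta if not p.at_edge and p.fwhm_um is not None]
    mean_ptb = float(np.mean([p.peak_to_bead for p in included])) if included else math.nan
    mean_w = float(np.mean([p.fwhm_um for p in included])) if included else math.nan
    return AnimalRecord(
        animal_id=animal_id,
        genotype=genotype,
        bead_intensity=bead_intensity,
        puncta=list(puncta),
        cord_length_um=span,
        mean_peak_to_bead=mean_ptb,
        mean_fwhm_um=mean_w,
        density_per_10um=density_per_10um(len(puncta), span),
    )
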