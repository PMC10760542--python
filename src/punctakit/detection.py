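"""Punctum detection on a 1D linescan.

The detection chain is: Gaussian smoothing (``sigma_px``), Phansalkar local
adaptive thresholding on min-max-rescaled intensities, and minimum-size
filtering of supra-threshold runs. Although the originating protocol runs
inside an image-analysis GUI, every reported metric (FWHM along the cord,
density per 10 um) is one-dimensional, so thresholding operates on the
extracted profile; a 2D mode is deliberately out of scope.

The Phansalkar threshold at index i is

    t_i = m_i * (1 + p * exp(-q * m_i) + k * (s_i / r - 1))

where m_i and s_i are the mean and population standard deviation of the
rescaled intensities in the window [i - radius, i + radius] (reflected at
the profile ends). A sample is foreground iff its rescaled intensity is
strictly greater than t_i. The ``p * exp(-q * m)`` term raises the threshold
in dim regions, which is what lets the method reject background that global
methods (Otsu) accept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d, uniform_filter1d

from punctakit.image_io import IntensityProfile

__all__ = [
    "DetectionParams",
    "Segment",
    "smooth_profile",
    "phansalkar_threshold",
    "segment_puncta",
    "detect_puncta",
]


@dataclass(frozen=True)
class DetectionParams:
    """Detection parameters.

    Defaults follow the protocol settings (minimum puncta size = 10,
    radius = 2, sigma = 0.5, method = Phansalkar); the Phansalkar constants
    k, r, p, q are the method's published defaults. All length-like
    parameters are in pixels: radius and sigma are pixel-denominated in the
    protocol, so the minimum size is read as pixels too.
    """

    sigma_px: float = 0.5
    radius_px: int = 2
    min_size_px: int = 10
    k: float = 0.25
    r: float = 0.5
    p: float = 2.0
    q: float = 10.0

    def __post_init__(self) -> None:
        if not np.isfinite([self.sigma_px, self.k, self.r, self.p, self.q]).all():
            raise ValueError("detection parameters must be finite")
        if self.sigma_px < 0:
            raise ValueError("sigma_px must be >= 0")
        if self.radius_px < 1:
            raise ValueError("radius_px must be a positive integer")
        if self.min_size_px < 1:
            raise ValueError("min_size_px must be a positive integer")
        if not (0 < self.r <= 1):
            raise ValueError("r must be in (0, 1]")


@dataclass(frozen=True)
class Segment:
    """Inclusive index range of one supra-threshold run on the profile."""

    start_idx: int
    end_idx: int

    def __post_init__(self) -> None:
        if not (0 <= self.start_idx <= self.end_idx):
            raise ValueError("need 0 <= start_idx <= end_idx")

    @property
    def extent_px(self) -> int:
        return self.end_idx - self.start_idx + 1


def smooth_profile(profile: IntensityProfile, sigma_px: float) -> IntensityProfile:
    """Gaussian-smooth a profile (reflect boundaries); sigma 0 is identity."""
    if sigma_px < 0:
        raise ValueError("sigma_px must be >= 0")
    if sigma_px == 0:
        return profile
    smoothed = gaussian_filter1d(profile.intensities, sigma=sigma_px, mode="reflect")
    return profile.with_intensities(smoothed)


def phansalkar_threshold(profile: IntensityProfile, params: DetectionParams) -> np.ndarray:
    """Phansalkar local adaptive threshold mask of the profile.

    Returns a boolean mask the length of the profile; True marks foreground.
    A flat profile (no dynamic range to rescale) yields an all-False mask
    with a warning rather than an error.
    """
    intens = profile.intensities
    window = 2 * params.radius_px + 1
    if intens.size < window:
        raise ValueError(
            f"profile length {intens.size} shorter than threshold window {window}"
        )
    lo, hi = float(intens.min()), float(intens.max())
    if hi == lo:
        warnings.warn("flat profile: no puncta detectable", stacklevel=2)
        return np.zeros(intens.size, dtype=bool)
    scaled = (intens - lo) / (hi - lo)
    # clamp: the filter can return tiny negative means on all-zero plateaus
    m = np.maximum(uniform_filter1d(scaled, size=window, mode="reflect"), 0.0)
    m2 = uniform_filter1d(scaled * scaled, size=window, mode="reflect")
    s = np.sqrt(np.maximum(m2 - m * m, 0.0))  # population std over the window
    t = m * (1.0 + params.p * np.exp(-params.q * m) + params.k * (s / params.r - 1.0))
    return scaled > t


def segment_puncta(mask: np.ndarray, min_size_px: int) -> list[Segment]:
    """Maximal runs of True at least ``min_size_px`` long, ordered by start."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2] - 1
    return [
        Segment(int(a), int(b))
        for a, b in zip(starts, ends)
        if b - a + 1 >= min_size_px
    ]


def detect_puncta(
    profile: IntensityProfile, params: DetectionParams | None = None
) -> tuple[IntensityProfile, np.ndarray, list[Segment]]:
    """Run the full detection chain: smooth, threshold, segment.

    Returns ``(smoothed_profile, mask, segments)``. The smoothed profile is
    the one on which downstream measurements (peak, baseline, FWHM) are made,
    so that detection and measurement see the same signal.
    """
    params = params or DetectionParams()
    smoothed = smooth_profile(profile, params.sigma_px)
    mask = phansalkar_threshold(smoothed, params)
    segments = segment_puncta(mask, params.min_size_px)
    return smoothed, mask, segments
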