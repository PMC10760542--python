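import numpy as np
import pytest

from punctakit.image_io import IntensityProfile


def make_profile(intensities, um_per_px=0.1) -> IntensityProfile:
    intensities = np.asarray(intensities, dtype=float)
    return IntensityProfile(
        positions=np.arange(intensities.size) * um_per_px,
        intensities=intensities,
        um_per_px=um_per_px,
    )


def gaussian_profile(sigma_um, amplitude=100.0, baseline=0.0, step_um=0.1, half_span_um=None):
    """Single Gaussian bump centered on the profile."""
    if half_span_um is None:
        half_span_um = 8 * sigma_um
    n_half = int(round(half_span_um / step_um))
    x = np.arange(2 * n_half + 1) * step_um
    center = x[n_half]
    return make_profile(
        baseline + amplitude * np.exp(-0.5 * ((x - center) / sigma_um) ** 2),
        um_per_px=step_um,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
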