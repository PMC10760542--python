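import math

import numpy as np
import pytest

from punctakit.detection import Segment
from punctakit.image_io import IntensityProfile
from punctakit.metrics import (
    aggregate_animal,
    density_per_10um,
    estimate_baseline,
    fwhm,
    measure_peak,
    measure_puncta,
    peak_to_bead,
)

from conftest import gaussian_profile, make_profile

FWHM_PER_SIGMA = 2 * math.sqrt(2 * math.log(2))


def dense_fwhm_oracle(profile, peak_pos, peak_int, baseline, step=1e-4):
    """Crossing positions found on a densely resampled profile."""
    half = baseline + (peak_int - baseline) / 2
    x = np.arange(profile.positions[0], profile.positions[-1], step)
    y = np.interp(x, profile.positions, profile.intensities)
    pk = np.argmin(np.abs(x - peak_pos))
    left = pk
    while left > 0 and y[left] >= half:
        left -= 1
    right = pk
    while right < len(x) - 1 and y[right] >= half:
        right += 1
    return x[right] - x[left]


class TestMeasurePeak:
    def test_simple_maximum(self):
        prof = make_profile([10, 20, 30, 20], um_per_px=1.0)
        pos, val = measure_peak(prof, Segment(0, 3))
        assert (pos, val) == (2.0, 30.0)

    def test_plateau_tie_breaks_to_earlier(self):
        prof = make_profile([5, 9, 9, 5], um_per_px=1.0)
        pos, val = measure_peak(prof, Segment(0, 3))
        assert (pos, val) == (1.0, 9.0)

    def test_matches_linear_scan_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(5, 60))
            prof = make_profile(rng.uniform(0, 100, n))
            a = int(rng.integers(0, n - 1))
            b = int(rng.integers(a, n))
            pos, val = measure_peak(prof, Segment(a, b))
            best_idx, best_val = a, prof.intensities[a]
            for i in range(a, b + 1):
                if prof.intensities[i] > best_val:
                    best_idx, best_val = i, prof.intensities[i]
            assert val == best_val
            assert pos == prof.positions[best_idx]


class TestEstimateBaseline:
    def test_single_foreground_sample(self):
        prof = make_profile([1, 1, 9, 1, 1])
        mask = np.array([False, False, True, False, False])
        assert estimate_baseline(prof, mask) == 1.0

    def test_even_count_median(self):
        prof = make_profile([1, 2, 3, 4, 50])
        mask = np.array([False, False, False, False, True])
        assert estimate_baseline(prof, mask) == 2.5

    def test_matches_sort_based_oracle(self, rng):
        for _ in range(50):
            vals = rng.uniform(0, 10, 31)
            mask = rng.random(31) < 0.4
            if mask.all():
                mask[0] = False
            got = estimate_baseline(make_profile(vals), mask)
            bg = sorted(vals[~mask])
            n = len(bg)
            expected = bg[n // 2] if n % 2 else (bg[n // 2 - 1] + bg[n // 2]) / 2
            assert got == pytest.approx(expected)

    def test_all_foreground_errors(self):
        prof = make_profile([1, 2, 3])
        with pytest.raises(ValueError, match="no background"):
            estimate_baseline(prof, np.ones(3, dtype=bool))


class TestFwhm:
    @pytest.mark.parametrize("sigma_um", [0.5, 1.0, 2.0])
    def test_gaussian_closed_form(self, sigma_um):
        prof = gaussian_profile(sigma_um, amplitude=100.0, step_um=0.1)
        pk = int(np.argmax(prof.intensities))
        got = fwhm(prof, prof.positions[pk], prof.intensities[pk], 0.0)
        assert got == pytest.approx(FWHM_PER_SIGMA * sigma_um, rel=0.01)

    def test_triangle_geometry(self):
        # linear rise 0 -> 100 over 0 -> 5 um, back to 0 at 10 um
        x = np.arange(0, 10.5, 0.5)
        y = 100 - 20 * np.abs(x - 5)
        prof = make_profile(y, um_per_px=0.5)
        got = fwhm(prof, 5.0, 100.0, 0.0)
        assert got == pytest.approx(5.0, abs=1e-9)

    def test_triangle_on_raised_baseline_matches_dense_oracle(self):
        x = np.arange(0, 10.5, 0.5)
        y = 20 + (100 - 20 * np.abs(x - 5))
        prof = make_profile(y, um_per_px=0.5)
        got = fwhm(prof, 5.0, 120.0, 20.0)  # half level 70
        oracle = dense_fwhm_oracle(prof, 5.0, 120.0, 20.0)
        assert got == pytest.approx(oracle, abs=1e-3)
        assert got == pytest.approx(5.0, abs=1e-9)

    def test_edge_truncated_returns_none(self):
        y = np.array([80.0, 90, 100, 60, 20, 5, 5, 5])
        prof = make_profile(y, um_per_px=1.0)
        assert fwhm(prof, 2.0, 100.0, 0.0) is None  # left walk exits

    def test_non_positive_prominence_errors(self):
        prof = make_profile([1.0, 2, 3, 2, 1])
        with pytest.raises(ValueError, match="prominence"):
            fwhm(prof, 2 * 0.1, 1.0, 2.0)

    def test_spatial_rescale_equivariance(self):
        for c in (0.5, 3.0):
            p1 = gaussian_profile(1.0, step_um=0.1)
            p2 = IntensityProfile(
                positions=p1.positions * c,
                intensities=p1.intensities,
                um_per_px=p1.um_per_px * c,
            )
            pk = int(np.argmax(p1.intensities))
            w1 = fwhm(p1, p1.positions[pk], p1.intensities[pk], 0.0)
            w2 = fwhm(p2, p2.positions[pk], p2.intensities[pk], 0.0)
            assert w2 == pytest.approx(c * w1, abs=1e-9)

    def test_affine_intensity_invariance(self):
        p1 = gaussian_profile(1.0, amplitude=50.0, baseline=10.0, step_um=0.1)
        pk = int(np.argmax(p1.intensities))
        w1 = fwhm(p1, p1.positions[pk], p1.intensities[pk], 10.0)
        a, b = 2.5, 7.0
        p2 = p1.with_intensities(a * p1.intensities + b)
        w2 = fwhm(p2, p2.positions[pk], p2.intensities[pk], a * 10.0 + b)
        assert w2 == pytest.approx(w1, abs=1e-9)


class TestPeakToBead:
    def test_ratio(self):
        assert peak_to_bead(200.0, 100.0) == 2.0
        assert peak_to_bead(100.0, 100.0) == 1.0

    def test_gain_cancellation(self):
        for c in (0.1, 7.0):
            assert peak_to_bead(c * 150.0, c * 80.0) == pytest.approx(peak_to_bead(150.0, 80.0))

    def test_invalid_bead_errors(self):
        with pytest.raises(ValueError, match="bead"):
            peak_to_bead(10.0, 0.0)


class TestDensity:
    @pytest.mark.parametrize("n,length,expected", [(5, 50.0, 1.0), (0, 30.0, 0.0), (12, 60.0, 2.0)])
    def test_values(self, n, length, expected):
        assert density_per_10um(n, length) == expected

    def test_non_positive_length_errors(self):
        with pytest.raises(ValueError):
            density_per_10um(3, 0.0)

    def test_integer_count_recovery(self, rng):
        for _ in range(20):
            n = int(rng.integers(0, 40))
            length = float(rng.uniform(10, 200))
            d = density_per_10um(n, length)
            assert round(d * length / 10) == n


class TestAggregateAnimal:
    def _punctum_profile(self):
        # two clean Gaussians on a 60 um cord
        x = np.arange(0, 60.0, 0.1)
        y = 5 + 100 * np.exp(-0.5 * ((x - 20) / 0.85) ** 2) + 300 * np.exp(
            -0.5 * ((x - 40) / 0.85) ** 2
        )
        return make_profile(y, um_per_px=0.1)

    def test_means_and_density(self):
        prof = self._punctum_profile()
        mask = prof.intensities > 30
        segs = [Segment(*np.flatnonzero(mask & (np.abs(prof.positions - c) < 5))[[0, -1]]) for c in (20, 40)]
        puncta = measure_puncta(prof, mask, segs, bead_intensity=100.0)
        rec = aggregate_animal(prof, puncta, 100.0, animal_id="a1", genotype="wt")
        ptbs = [p.peak_to_bead for p in puncta]
        assert rec.mean_peak_to_bead == pytest.approx(np.mean(ptbs))
        assert rec.density_per_10um == pytest.approx(10 * 2 / prof.span_um)
        assert rec.cord_length_um == pytest.approx(prof.span_um)

    def test_two_peak_to_bead_values_average(self):
        prof = self._punctum_profile()
        mask = prof.intensities > 30
        segs = [Segment(*np.flatnonzero(mask & (np.abs(prof.positions - c) < 5))[[0, -1]]) for c in (20, 40)]
        puncta = measure_puncta(prof, mask, segs, bead_intensity=100.0)
        # bead 100: peaks ~105 and ~305 -> mean peak-to-bead ~2.05
        assert aggregate_animal(prof, puncta, 100.0).mean_peak_to_bead == pytest.approx(2.05, rel=0.02)

    def test_edge_only_punctum_counts_for_density_not_means(self):
        # punctum truncated by the left profile end
        x = np.arange(0, 30.0, 0.1)
        y = 5 + 100 * np.exp(-0.5 * (x / 2.0) ** 2)
        prof = make_profile(y, um_per_px=0.1)
        mask = prof.intensities > 30
        seg = Segment(0, int(np.flatnonzero(mask)[-1]))
        puncta = measure_puncta(prof, mask, [seg], bead_intensity=50.0)
        assert puncta[0].at_edge
        rec = aggregate_animal(prof, puncta, 50.0)
        assert rec.density_per_10um == pytest.approx(10 * 1 / prof.span_um)
        assert math.isnan(rec.mean_fwhm_um)
        assert math.isnan(rec.mean_peak_to_bead)

    def test_empty_puncta_list(self):
        prof = make_profile(np.full(20, 5.0), um_per_px=1.0)
        rec = aggregate_animal(prof, [], 100.0)
        assert rec.density_per_10um == 0.0
        assert math.isnan(rec.mean_fwhm_um)


class TestLocalEdgesBaseline:
    def test_local_baseline_uses_flanking_samples(self):
        x = np.arange(0, 20.0, 0.1)
        y = 10 + 100 * np.exp(-0.5 * ((x - 10) / 0.85) ** 2)
        prof = make_profile(y, um_per_px=0.1)
        mask = prof.intensities > 40
        idx = np.flatnonzero(mask)
        seg = Segment(int(idx[0]), int(idx[-1]))
        local = measure_puncta(prof, mask, [seg], 100.0, baseline_method="local_edges")
        assert local[0].baseline == pytest.approx(
            min(prof.intensities[idx[0] - 1], prof.intensities[idx[-1] + 1])
        )
        with pytest.raises(ValueError, match="baseline"):
            measure_puncta(prof, mask, [seg], 100.0, baseline_method="bogus")
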