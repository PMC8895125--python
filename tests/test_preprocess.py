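import numpy as np
import pytest

from acidmap.exceptions import (NormalizationError, PeakBoundsError,
                                WindowError)
from acidmap.io import RamanSpectrum
from acidmap.preprocess import (crop_and_vectorize, featurize,
                                find_peak1_bounds, normalize, peak1_area)
from acidmap.simulate import ChipModel, canonical_grid, synth_spectrum


def brute_force_bounds(s, lo=360.0, hi=390.0, span=150.0):
    """Independent exhaustive-scan oracle for the peak-1 endpoint search."""
    win = [i for i in range(len(s)) if lo < s.shifts[i] < hi]
    i2 = min(win, key=lambda i: (s.intensities[i], s.shifts[i]))
    y2 = s.intensities[i2]
    left = [i for i in range(len(s))
            if s.shifts[i2] - span <= s.shifts[i] < s.shifts[i2]]
    ipk = max(left, key=lambda i: (s.intensities[i], -s.shifts[i]))
    x1 = None
    for j in range(ipk - 1, -1, -1):
        if s.intensities[j] <= y2:
            x1 = j
            break
    return x1, i2


class TestPeak1Bounds:
    def test_symmetric_triangle(self):
        grid = canonical_grid()
        intens = np.clip(100.0 - 2.0 * np.abs(grid - 311.0), 0.0, None)
        s = RamanSpectrum(grid, intens)
        b = find_peak1_bounds(s)
        assert b.y2 == 0.0
        assert b.x1 < 311.0 < b.x2
        assert abs((311.0 - b.x1) - (b.x2 - 311.0)) <= np.diff(grid)[0] + 1e-9

    def test_matches_exhaustive_scan_on_simulated_spectra(self, reporter):
        for seed in range(5):
            chip = ChipModel(f"c{seed}", noise_sigma=6.0)
            s = synth_spectrum(chip, reporter, 6.0 + 0.3 * seed, rng=seed)
            b = find_peak1_bounds(s)
            i1, i2 = brute_force_bounds(s)
            assert (b.i1, b.i2) == (i1, i2)

    def test_strictly_increasing_spectrum_rejected(self):
        grid = canonical_grid()
        s = RamanSpectrum(grid, np.linspace(1.0, 500.0, grid.size))
        with pytest.raises(PeakBoundsError):
            find_peak1_bounds(s)

    def test_spectrum_not_covering_window_rejected(self):
        s = RamanSpectrum(np.linspace(400, 1700, 300), np.ones(300))
        with pytest.raises(PeakBoundsError):
            find_peak1_bounds(s)


class TestPeak1Area:
    def test_rectangular_pulse_analytic(self):
        shifts = np.arange(0.0, 500.0)
        intens = np.where((shifts >= 300) & (shifts <= 340), 5.0, 0.0)
        s = RamanSpectrum(shifts, intens)
        from acidmap.preprocess import Peak1Bounds

        b = Peak1Bounds(x1=300.0, x2=340.0, y2=0.0, i1=300, i2=340)
        assert peak1_area(s, b) == pytest.approx(5.0 * 40.0)

    def test_zero_segment(self):
        shifts = np.arange(0.0, 500.0)
        s = RamanSpectrum(shifts, np.zeros(500))
        from acidmap.preprocess import Peak1Bounds

        b = Peak1Bounds(x1=300.0, x2=340.0, y2=0.0, i1=300, i2=340)
        assert peak1_area(s, b) == 0.0

    def test_against_oversampled_oracle(self, reporter, ideal_chip):
        """Trapezoid on the canonical grid vs 10x-oversampled integration."""
        coarse = canonical_grid()
        s = synth_spectrum(ideal_chip, reporter, 6.5, grid=coarse, noise=False)
        b = find_peak1_bounds(s)
        step = np.diff(coarse)[0]
        fine = np.arange(b.x1, b.x2 + step / 10.0 / 2, step / 10.0)
        sf = synth_spectrum(ideal_chip, reporter, 6.5, grid=fine, noise=False)
        oracle = np.trapezoid(sf.intensities, sf.shifts)
        assert peak1_area(s, b) == pytest.approx(oracle, rel=0.01)


class TestCropAndNormalize:
    def test_output_length_256(self, reporter, ideal_chip):
        s = synth_spectrum(ideal_chip, reporter, 7.0, noise=False)
        assert crop_and_vectorize(s).values.size == 256

    def test_truncation_invariance_above_1700(self, reporter, ideal_chip):
        s = synth_spectrum(ideal_chip, reporter, 7.0, noise=False)
        mod = RamanSpectrum(s.shifts, s.intensities.copy())
        mod.intensities[s.shifts > 1700.0] += 500.0
        assert np.array_equal(
            crop_and_vectorize(s).values, crop_and_vectorize(mod).values
        )

    def test_window_blind_to_peak1_region(self, reporter, ideal_chip):
        s = synth_spectrum(ideal_chip, reporter, 7.0, noise=False)
        mod = RamanSpectrum(s.shifts, s.intensities.copy())
        mod.intensities[:79] *= 1.5  # below the 80th point
        a = crop_and_vectorize(s)
        m = crop_and_vectorize(mod)
        assert np.array_equal(a.values, m.values)
        assert m.peak1_area != a.peak1_area

    def test_short_spectrum_rejected(self):
        s = RamanSpectrum(np.linspace(0, 2000, 300), np.ones(300))
        with pytest.raises(WindowError):
            crop_and_vectorize(s)

    def test_unit_area_is_identity(self, reporter, ideal_chip):
        s = synth_spectrum(ideal_chip, reporter, 7.0, noise=False)
        v = crop_and_vectorize(s)
        v.peak1_area = 1.0
        assert np.array_equal(normalize(v).values, v.values)

    def test_gain_invariance_noise_free(self, reporter):
        base = ChipModel("g1", gain=1.0, noise_sigma=0.0)
        scaled = ChipModel("g3", gain=3.0, noise_sigma=0.0)
        v1 = featurize(synth_spectrum(base, reporter, 6.2, noise=False))
        v3 = featurize(synth_spectrum(scaled, reporter, 6.2, noise=False))
        assert np.allclose(v1.values, v3.values, rtol=1e-10)

    def test_nonpositive_area_rejected(self, reporter, ideal_chip):
        s = synth_spectrum(ideal_chip, reporter, 7.0, noise=False)
        v = crop_and_vectorize(s)
        v.peak1_area = 0.0
        with pytest.raises(NormalizationError):
            normalize(v)

    def test_normalized_vectors_vary_with_ph_and_offset(self, reporter):
        """pH moves the normalized vector; so does a chip's calibration offset."""
        plain = ChipModel("p", noise_sigma=0.0)
        offset = ChipModel("o", ratio_offset=0.4, noise_sigma=0.0)
        v_65 = featurize(synth_spectrum(plain, reporter, 6.5, noise=False)).values
        v_70 = featurize(synth_spectrum(plain, reporter, 7.0, noise=False)).values
        v_off = featurize(synth_spectrum(offset, reporter, 6.5, noise=False)).values
        assert not np.allclose(v_65, v_70)
        assert not np.allclose(v_65, v_off)
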