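import numpy as np
import pytest

from acidmap.baseline import (RatioCalibration, _logistic4, fit_chip_linear,
                              fit_global_nonlinear, intensity_ratio,
                              load_calibration, master_calibration,
                              predict_ph_regression, save_calibration)
from acidmap.exceptions import FitError, RatioError
from acidmap.io import RamanSpectrum
from acidmap.simulate import ChipModel, canonical_grid, synth_spectrum


def _twin_peak_spectrum(h527, h311):
    grid = canonical_grid()
    intens = (
        h311 * np.exp(-0.5 * ((grid - 311.0) / 8.0) ** 2)
        + h527 * np.exp(-0.5 * ((grid - 527.0) / 8.0) ** 2)
    )
    return RamanSpectrum(grid, intens)


class TestIntensityRatio:
    def test_equal_heights_give_unity(self):
        s = _twin_peak_spectrum(80.0, 80.0)
        # grid sampling is not centered on either peak; ~0.5% asymmetry remains
        assert intensity_ratio(s) == pytest.approx(1.0, rel=1e-2)

    def test_gain_invariance(self):
        s1 = _twin_peak_spectrum(60.0, 90.0)
        s2 = RamanSpectrum(s1.shifts, s1.intensities * 7.5)
        assert intensity_ratio(s1) == pytest.approx(intensity_ratio(s2), rel=1e-12)

    def test_monotone_decreasing_in_ph(self, reporter, ideal_chip):
        phs = np.arange(5.0, 8.01, 0.25)
        rs = [
            intensity_ratio(synth_spectrum(ideal_chip, reporter, p, noise=False))
            for p in phs
        ]
        assert np.all(np.diff(rs) < 0)

    def test_nonpositive_reference_rejected(self):
        grid = canonical_grid()
        s = RamanSpectrum(grid, np.ones(grid.size))  # flat: zero corrected height
        with pytest.raises(RatioError):
            intensity_ratio(s)


class TestChipLinear:
    def test_exact_recovery_on_linear_data(self):
        r = np.array([2.0, 1.5, 1.0, 0.5])
        ph = -2.0 * r + 9.0
        a, b, sd = fit_chip_linear(r, ph)
        assert (a, b) == (pytest.approx(-2.0), pytest.approx(9.0))
        assert sd == pytest.approx(0.0, abs=1e-12)

    def test_duplicated_points_leave_fit_unchanged(self):
        r = np.array([2.0, 1.0, 0.5, 1.5])
        ph = -1.5 * r + 8.5 + np.array([0.05, -0.02, 0.01, -0.04])
        a1, b1, _ = fit_chip_linear(r, ph)
        a2, b2, _ = fit_chip_linear(np.tile(r, 2), np.tile(ph, 2))
        assert a1 == pytest.approx(a2) and b1 == pytest.approx(b2)

    def test_single_ph_level_rejected(self):
        with pytest.raises(FitError):
            fit_chip_linear(np.array([1.0, 1.1]), np.array([6.5, 6.5]))

    def test_noise_free_simulated_chip_residuals_small(self, reporter):
        chip = ChipModel("lin", noise_sigma=0.0)
        phs = np.arange(5.0, 8.01, 0.25)
        rs = np.array(
            [intensity_ratio(synth_spectrum(chip, reporter, p, noise=False))
             for p in phs]
        )
        _, _, sd = fit_chip_linear(rs, phs)
        assert sd < 0.05


class TestGlobalNonlinear:
    def test_parameter_recovery_from_known_logistic(self):
        ph = np.linspace(5.0, 8.0, 40)
        true = (3.0, 0.8, 6.6, 0.9)
        r = _logistic4(ph, *true)
        calib = fit_global_nonlinear(r, ph)
        assert np.allclose(calib.global_params, true, rtol=1e-4)
        # inversion at the midpoint returns the midpoint pH
        r_mid = 0.8 + (3.0 - 0.8) / 2.0
        assert calib.predict_global(r_mid) == pytest.approx(6.6, abs=1e-6)

    def test_single_chip_noise_free_mae_small(self, reporter):
        chip = ChipModel("solo", noise_sigma=0.0)
        phs = np.repeat(np.arange(5.0, 8.01, 0.25), 2)
        rs = np.array(
            [intensity_ratio(synth_spectrum(chip, reporter, p, noise=False))
             for p in phs]
        )
        calib = fit_global_nonlinear(rs, phs)
        pred = calib.predict_global(rs)
        assert np.mean(np.abs(pred - phs)) < 0.05

    def test_offset_chips_degrade_global_fit(self, small_db):
        """Chip calibration offsets bias a chip-agnostic model; per-chip
        lines do not - the motivating failure of single-curve calibration."""
        from acidmap.pipeline import dataset_ratios, fit_ratio_calibration

        dataset, chips = small_db
        ratios = dataset_ratios(dataset)
        table = dataset.table
        mask = np.ones(len(dataset), dtype=bool)
        calib = fit_ratio_calibration(ratios, table, mask)
        tags = table["ph_tag"].to_numpy()
        glob = np.asarray(calib.predict_global(ratios))
        per = np.array(
            [calib.predict_chip(c, r) for c, r in zip(table["chip_id"], ratios)]
        )
        assert np.mean(np.abs(per - tags)) < 0.5 * np.mean(np.abs(glob - tags))

    def test_inverted_model_is_monotone(self):
        ph = np.linspace(5.0, 8.0, 40)
        r = _logistic4(ph, 3.0, 0.8, 6.6, 0.9)
        calib = fit_global_nonlinear(r, ph)
        rs = np.linspace(0.5, 3.5, 100)
        preds = np.asarray(calib.predict_global(rs))
        assert np.all(np.diff(preds) <= 1e-9)  # larger ratio never maps higher

    def test_too_few_levels_rejected(self):
        with pytest.raises(FitError):
            fit_global_nonlinear(np.array([1, 2, 3.0]), np.array([5, 6, 7.0]))

    def test_predictions_clipped_to_calibrated_range(self):
        ph = np.linspace(5.0, 8.0, 40)
        r = _logistic4(ph, 3.0, 0.8, 6.6, 0.9)
        calib = fit_global_nonlinear(r, ph)
        assert calib.predict_global(50.0) == 5.0
        assert calib.predict_global(1e-6) == 8.0


class TestPrediction:
    def test_training_spectrum_of_linear_chip_recovers_tag(self, reporter):
        chip = ChipModel("lin", noise_sigma=0.0)
        phs = np.arange(5.0, 8.01, 0.25)
        specs = [synth_spectrum(chip, reporter, p, noise=False) for p in phs]
        rs = np.array([intensity_ratio(s) for s in specs])
        calib = RatioCalibration()
        calib.per_chip["lin"] = fit_chip_linear(rs, phs)
        pred = predict_ph_regression(calib, specs[6], chip_id="lin")
        assert pred == pytest.approx(phs[6], abs=0.05)

    def test_batch_prediction_order_independent(self):
        ph = np.linspace(5.0, 8.0, 30)
        r = _logistic4(ph, 3.0, 0.8, 6.6, 0.9)
        calib = fit_global_nonlinear(r, ph)
        rs = np.array([1.0, 1.7, 2.4])
        fwd = np.asarray(calib.predict_global(rs))
        rev = np.asarray(calib.predict_global(rs[::-1]))[::-1]
        assert np.array_equal(fwd, rev)

    def test_save_load_round_trip(self, tmp_path):
        ph = np.linspace(5.0, 8.0, 30)
        r = _logistic4(ph, 3.0, 0.8, 6.6, 0.9)
        calib = fit_global_nonlinear(r, ph)
        calib.per_chip["x"] = (-2.0, 9.0, 0.01)
        path = tmp_path / "calib.json"
        save_calibration(calib, str(path))
        back = load_calibration(str(path))
        assert back.per_chip == calib.per_chip
        assert back.global_params == pytest.approx(calib.global_params)


class TestMasterCalibration:
    def test_err_ordering_recoverable_from_baseline(self, reporter):
        """A group-a chip shows a larger 6.50 readout error than a group-c
        chip generated from the same seed stream."""
        from acidmap.evaluation import assign_chip_group
        from acidmap.simulate import synth_chip

        calib = master_calibration(reporter)
        chip_a = synth_chip("a", seed=21)
        chip_c = synth_chip("c", seed=21)
        errs = {}
        for chip in (chip_a, chip_c):
            specs = [synth_spectrum(chip, reporter, 6.50, rng=i) for i in range(5)]
            errs[chip.group] = assign_chip_group(specs, calib, chip.chip_id).err
        assert abs(errs["a"]) > abs(errs["c"])
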