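import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from acidmap.simulate import (DEFAULT_GROUP_MIX, GROUP_BOUNDS,
                              ChipModel, build_database,
                              canonical_grid, group_from_err,
                              protonation_fraction, synth_chip,
                              synth_peak_amplitudes, synth_phantom,
                              synth_spectrum)


class TestGrid:
    def test_window_semantics(self):
        g = canonical_grid()
        assert g.size == 400
        assert g[79] == pytest.approx(390.0)   # 80th point, 1-based
        assert g[334] == pytest.approx(1700.0)  # 335th point

    def test_uniform_spacing(self):
        g = canonical_grid()
        assert np.allclose(np.diff(g), np.diff(g)[0])


class TestProtonation:
    def test_half_at_pka(self):
        assert protonation_fraction(6.7, 6.7) == pytest.approx(0.5)

    def test_acid_limit(self):
        assert protonation_fraction(3.7, 6.7) == pytest.approx(0.999, abs=1e-3)

    def test_direct_evaluation(self):
        assert protonation_fraction(8.0, 6.7) == pytest.approx(
            1.0 / (1.0 + 10**1.3), rel=1e-12
        )

    @given(st.floats(2.0, 12.0))
    def test_strictly_decreasing(self, ph):
        assert protonation_fraction(ph + 0.1, 6.7) < protonation_fraction(ph, 6.7)


class TestSynthSpectrum:
    def test_enhancement_anchors_exact(self, ideal_chip, reporter):
        a2 = synth_peak_amplitudes(ideal_chip, reporter, 2.0)
        a8 = synth_peak_amplitudes(ideal_chip, reporter, 8.0)
        assert np.allclose(a2 / a8, reporter.enhancement_max)
        # the internal standard is flat, the olefin stretch gains 3.4-fold
        assert a2[0] / a8[0] == pytest.approx(1.0)
        assert a2[4] / a8[4] == pytest.approx(3.4)

    def test_ph8_amplitude_equals_base_times_gain(self, reporter):
        chip = ChipModel("g2", gain=2.0, baseline_params=(0, 0, 0), noise_sigma=0.0)
        a8 = synth_peak_amplitudes(chip, reporter, 8.0)
        assert np.allclose(a8, np.asarray(reporter.base_amplitudes) * 2.0)

    def test_responsive_amplitudes_monotone_in_ph(self, ideal_chip, reporter):
        phs = np.linspace(2.0, 9.0, 30)
        amps = np.array([synth_peak_amplitudes(ideal_chip, reporter, p) for p in phs])
        diffs = np.diff(amps, axis=0)
        assert np.all(diffs[:, 1:] <= 1e-9)           # pH-responsive peaks fall
        assert np.allclose(amps[:, 0], amps[0, 0])    # 311 1/cm constant

    def test_spectrum_deterministic_under_seed(self, reporter):
        chip = ChipModel("n", noise_sigma=5.0)
        s1 = synth_spectrum(chip, reporter, 6.5, rng=42)
        s2 = synth_spectrum(chip, reporter, 6.5, rng=42)
        assert np.array_equal(s1.intensities, s2.intensities)

    def test_noise_free_spectrum_nonnegative_finite(self, ideal_chip, reporter):
        s = synth_spectrum(ideal_chip, reporter, 5.0, noise=False)
        assert np.all(s.intensities >= 0) and np.all(np.isfinite(s.intensities))


class TestSynthChip:
    @pytest.mark.parametrize("group", sorted(GROUP_BOUNDS))
    def test_target_group_achieved(self, group):
        chip = synth_chip(group, seed=5)
        lo, hi = GROUP_BOUNDS[group]
        assert chip.group == group
        assert lo - 1e-2 < chip.err < hi + 1e-2
        assert group_from_err(chip.err) == group

    def test_same_seed_identical_parameters(self):
        c1 = synth_chip("b", seed=9)
        c2 = synth_chip("b", seed=9)
        assert c1.gain == c2.gain
        assert c1.ratio_offset == c2.ratio_offset
        assert np.array_equal(c1.peak_factors, c2.peak_factors)


class TestGroupClosure:
    @pytest.mark.parametrize(
        "err,group",
        [(0.6, "a"), (0.5, "b"), (0.3, "b"), (0.1, "c"), (0.0, "c"),
         (-0.1, "c"), (-0.15, "d"), (-0.2, "e"), (-0.3, "e")],
    )
    def test_boundary_closure(self, err, group):
        assert group_from_err(err) == group

    @given(st.floats(-2.0, 2.0, allow_nan=False))
    def test_every_err_lands_in_exactly_one_group(self, err):
        assert group_from_err(err) in "abcde"


class TestBuildDatabase:
    def test_small_database_composition(self, small_db):
        dataset, chips = small_db
        assert len(dataset) == 5 * 13 * 4
        counts = dataset.counts()
        assert (counts == 4).all()
        assert counts.index.get_level_values("nominal_ph").nunique() == 13

    def test_single_chip_single_rep(self):
        dataset, _ = build_database(n_chips=1, reps=1, seed=0)
        assert len(dataset) == 13

    def test_group_mix_counts(self, small_db):
        _, chips = small_db
        mix = {"a": 1, "c": 4}
        _, chips2 = build_database(n_chips=5, reps=1, seed=3, group_mix=mix)
        got = sorted(c.group for c in chips2)
        assert got == ["a", "c", "c", "c", "c"]

    def test_default_mix_sums_to_full_batch(self):
        from acidmap.simulate import _group_sequence

        seq = _group_sequence(40, DEFAULT_GROUP_MIX)
        assert len(seq) == 40
        assert seq.count("c") > max(seq.count(g) for g in "abde")

    def test_label_noise_applied_to_tags(self, small_db):
        dataset, _ = small_db
        resid = dataset.table["ph_tag"] - dataset.table["nominal_ph"]
        assert 0.0 < resid.abs().mean() < 0.1

    def test_reproducible(self):
        d1, _ = build_database(n_chips=2, reps=2, seed=7)
        d2, _ = build_database(n_chips=2, reps=2, seed=7)
        assert np.array_equal(d1.spectra[5].intensities, d2.spectra[5].intensities)
        assert d1.table.equals(d2.table)


class TestPhantom:
    def test_no_tumor_all_neutral(self):
        f = synth_phantom(tumor_geometry="none", seed=0)
        assert not f.tumor_mask.any()
        assert np.all((f.ph >= 7.0) & (f.ph <= 7.5))

    def test_full_field_tumor(self):
        f = synth_phantom(tumor_geometry="full", seed=0)
        assert f.tumor_mask.all()
        assert np.all((f.ph >= 6.2) & (f.ph <= 6.8))

    def test_default_blob_mask_is_acidic_and_contiguous(self):
        from scipy import ndimage

        f = synth_phantom(seed=4)
        assert f.tumor_mask.any()
        assert np.all(f.ph[f.tumor_mask] < 7.0)
        assert np.all(f.ph[~f.tumor_mask] >= 7.0)
        labels, n = ndimage.label(f.tumor_mask)
        assert n == 1

    def test_beta_above_feasibility_threshold(self):
        f = synth_phantom(seed=2)
        assert np.all(f.beta_t >= 2.8)
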