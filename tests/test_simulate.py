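import numpy as np
import pytest
from scipy import stats

from dtiphysio.physio import cardiac_phase
from dtiphysio.simulate import (
    PerturbationSpec,
    PhantomSpec,
    make_scheme,
    repulsion_energy,
    simulate_dwi,
    simulate_physio,
    simulate_timing,
)


class TestScheme:
    def test_default_66_volume_two_shell(self, scheme60):
        assert scheme60.n_volumes == 66
        assert int(np.sum(scheme60.b == 700.0)) == 60
        assert int(np.sum(scheme60.b == 100.0)) == 6

    def test_six_directions_are_octahedral(self):
        scheme = make_scheme(n_dirs=6, n_low=1, b_low=0.0)
        g = scheme.g[scheme.is_high]
        dots = np.abs(g @ g.T)
        np.testing.assert_allclose(np.sort(np.unique(np.round(dots, 6))), [0.0, 1.0])

    def test_repulsion_lowers_energy_below_random_start(self, scheme60):
        rng = np.random.default_rng(0)  # same seed as the scheme's start
        start = rng.normal(size=(60, 3))
        start /= np.linalg.norm(start, axis=1, keepdims=True)
        assert repulsion_energy(scheme60.g[scheme60.is_high]) < repulsion_energy(start)

    def test_high_b_directions_unit_norm(self, scheme60):
        norms = np.linalg.norm(scheme60.g[scheme60.is_high], axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-9)


class TestPhysioSim:
    def test_zero_variability_gives_exact_intervals(self):
        _, beats = simulate_physio(60.0, hr_std=0.0, seed=0)
        np.testing.assert_allclose(np.diff(beats), 1.0, atol=1e-9)

    def test_fixed_seed_is_bit_identical(self):
        rec1, b1 = simulate_physio(60.0, seed=9)
        rec2, b2 = simulate_physio(60.0, seed=9)
        np.testing.assert_array_equal(rec1.cardiac, rec2.cardiac)
        np.testing.assert_array_equal(rec1.respiratory, rec2.respiratory)
        np.testing.assert_array_equal(b1, b2)

    def test_recording_precedes_scan_start(self):
        rec, _ = simulate_physio(30.0, pre_roll_s=10.0)
        assert rec.time[0] == pytest.approx(-10.0)
        assert rec.time[-1] >= 30.0


class TestTiming:
    def test_nongated_volume_tr_is_fixed(self):
        timing = simulate_timing("nongated", n_volumes=4, n_slices=12)
        np.testing.assert_allclose(np.diff(timing.t, axis=0), 8.5)
        assert np.ptp(timing.t[0]) < 8.5

    def test_nongated_interleaved_order(self):
        timing = simulate_timing("nongated", n_volumes=2, n_slices=6)
        np.testing.assert_array_equal(timing.slice_order, [0, 2, 4, 1, 3, 5])

    def test_gated_blocks_of_three_consume_17_cycles_for_50_slices(self):
        beats = np.arange(0.0, 600.0, 1.0)
        timing = simulate_timing("gated", n_volumes=2, n_slices=50, beat_times=beats)
        # ceil(50/3) = 17 cardiac cycles per volume
        assert timing.t[1, 0] - timing.t[0, 0] == pytest.approx(17.0)

    def test_gated_phases_cluster_nongated_phases_spread(self, physio_2min):
        rec, beats = physio_2min
        gated = simulate_timing("gated", n_volumes=6, n_slices=12, beat_times=beats)
        nongated = simulate_timing("nongated", n_volumes=6, n_slices=12)
        phi_g = cardiac_phase(beats, gated.t.ravel()).reshape(gated.t.shape)
        # shift nongated times into the beat span
        t_n = nongated.t + beats[0] + 1.0
        phi_n = cardiac_phase(beats, t_n.ravel()).reshape(t_n.shape)
        spread_g = np.max(np.std(phi_g, axis=0))
        spread_n = np.mean(np.std(phi_n, axis=0))
        assert spread_g < np.pi / 8  # < systole_window / 4
        assert spread_n > 4 * spread_g

    def test_gated_needs_enough_beats(self):
        with pytest.raises(ValueError, match="too short"):
            simulate_timing("gated", n_volumes=10, n_slices=12, beat_times=np.arange(5.0))


class TestForwardModel:
    def test_unperturbed_noiseless_signal_matches_closed_form(self, identity_dataset):
        ds = identity_dataset
        phantom = ds.truth["phantom"]
        d = ds.truth["tensor"][3, 3, 3]
        g = ds.scheme.g
        adc = (
            g[:, 0] ** 2 * d[0] + g[:, 1] ** 2 * d[1] + g[:, 2] ** 2 * d[2]
            + 2 * g[:, 0] * g[:, 1] * d[3] + 2 * g[:, 0] * g[:, 2] * d[4]
            + 2 * g[:, 1] * g[:, 2] * d[5]
        )
        np.testing.assert_allclose(
            ds.series.data[3, 3, 3], phantom.s0 * np.exp(-ds.scheme.b * adc), rtol=1e-12
        )

    def test_fixed_seed_dataset_is_bit_identical(self):
        from dtiphysio.scenarios import scenario_nongated_outlier

        a = scenario_nongated_outlier(seed=4)
        b = scenario_nongated_outlier(seed=4)
        np.testing.assert_array_equal(a.series.data, b.series.data)

    def test_rician_noise_moments(self, rng):
        """Sample mean/SD of the noisy magnitude match the Rician law at SNR 20."""
        s0, snr = 1000.0, 20.0
        sigma = s0 / snr
        n = 100_000
        signal = np.full(n, 650.0)
        noisy = np.hypot(signal + rng.normal(0, sigma, n), rng.normal(0, sigma, n))
        dist = stats.rice(b=650.0 / sigma, scale=sigma)
        assert np.mean(noisy) == pytest.approx(dist.mean(), rel=0.02)
        assert np.std(noisy) == pytest.approx(dist.std(), rel=0.02)

    def test_overdriven_perturbation_rejected(self, physio_2min):
        rec, beats = physio_2min
        phantom = PhantomSpec(shape=(4, 4, 6))
        scheme = make_scheme(n_dirs=10, n_low=2)  # 12 volumes fit in the recording
        timing = simulate_timing("nongated", n_volumes=12, n_slices=6)
        timing.t += 2.0  # keep every slice inside the beat span
        pert = PerturbationSpec(cardiac_lin=np.array([1.2, 0, 0, 0]))
        with pytest.raises(ValueError, match="non-positive"):
            simulate_dwi(phantom, scheme, timing, rec, beats, pert, snr=None)

    def test_dropout_confined_to_basal_slab(self):
        """FA bias from cardiac-locked dropout appears only where it acts."""
        from dtiphysio.pipeline import fit_models
        from dtiphysio.scenarios import build_dataset

        pert = PerturbationSpec(
            cardiac_lin=np.zeros(4), resp_lin=np.zeros(4), dropout_amplitude=0.5
        )
        ds = build_dataset(mode="nongated", pert=pert, snr=None, seed=6, b_low=0.0)
        fits = fit_models(ds.series, ds.scheme, ds.timing, models=("standard",))
        bias = np.abs(fits["standard"].fa_map - ds.truth["fa"])
        basal = ds.truth["basal_mask"]
        assert np.nanmax(bias[~basal]) < 1e-10
        assert np.nanmax(bias[basal]) > 0.01
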