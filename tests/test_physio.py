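import numpy as np
import pytest

from dtiphysio.io import PhysioRecording, SliceTiming
from dtiphysio.physio import (
    cardiac_phase,
    detect_cardiac_peaks,
    fourier_basis,
    phase_at_slices,
    respiratory_phase,
    sample_at_slices,
)


def _rec(cardiac, resp=None, fs=100.0, duration=60.0):
    t = np.arange(0, duration, 1 / fs)
    card = cardiac(t) if callable(cardiac) else cardiac
    rsp = resp(t) if callable(resp) else (resp if resp is not None else np.sin(0.6 * np.pi * t))
    return PhysioRecording(time=t, cardiac=card, respiratory=rsp, fs=fs)


class TestPeakDetection:
    def test_pure_1hz_sinusoid_gives_60_beats(self):
        rec = _rec(lambda t: np.sin(2 * np.pi * t))
        peaks = detect_cardiac_peaks(rec)
        assert 58 <= peaks.size <= 60  # edge beats may fall off the ends
        np.testing.assert_allclose(np.diff(peaks), 1.0, atol=0.011)

    def test_amplitude_noise_does_not_change_beat_count(self, rng):
        t = np.arange(0, 60, 0.01)
        clean = np.sin(2 * np.pi * t)
        noisy = clean * (1 + 0.1 * rng.normal(size=t.size))
        n_clean = detect_cardiac_peaks(_rec(clean)).size
        n_noisy = detect_cardiac_peaks(_rec(noisy)).size
        assert n_noisy == n_clean

    def test_flat_line_rejected(self):
        with pytest.raises(ValueError, match="flat"):
            detect_cardiac_peaks(_rec(np.zeros(6000)))

    def test_short_recording_rejected(self):
        with pytest.raises(ValueError, match="10 s"):
            detect_cardiac_peaks(_rec(lambda t: np.sin(2 * np.pi * t), duration=5.0))


class TestCardiacPhase:
    def test_zero_at_peak_pi_at_midpoint(self):
        peaks = np.array([0.0, 1.0, 2.0])
        assert cardiac_phase(peaks, np.array([1.0]))[0] == pytest.approx(0.0)
        assert cardiac_phase(peaks, np.array([0.5]))[0] == pytest.approx(np.pi)

    def test_irregular_beats_interpolate_linearly(self):
        # beats at 1.0, 2.2, 3.0 s: t=2.6 is the midpoint of [2.2, 3.0]
        peaks = np.array([1.0, 2.2, 3.0])
        assert cardiac_phase(peaks, np.array([2.6]))[0] == pytest.approx(np.pi)

    def test_query_outside_span_is_hard_error(self):
        with pytest.raises(ValueError, match="outside"):
            cardiac_phase(np.array([1.0, 2.0]), np.array([2.5]))


class TestRespiratoryPhase:
    def test_extremum_maps_to_histogram_upper_edge(self):
        rec = _rec(lambda t: np.sin(2 * np.pi * t), resp=lambda t: np.sin(0.6 * np.pi * t))
        # inhalation extremum of sin(0.6*pi*t): t where 0.6*pi*t = pi/2
        t_ext = 0.5 / 0.6
        phi = respiratory_phase(rec, np.array([t_ext]))[0]
        assert abs(((phi + np.pi) % (2 * np.pi)) - np.pi) == pytest.approx(np.pi, abs=0.15)

    def test_inhale_and_exhale_occupy_disjoint_half_ranges(self):
        rec = _rec(lambda t: np.sin(2 * np.pi * t))
        t = np.arange(5, 55, 0.05)
        phi = respiratory_phase(rec, t)
        resp = np.interp(t, rec.time, rec.respiratory)
        dresp = np.gradient(resp, t)
        strong = np.abs(dresp) > 0.5 * np.max(np.abs(dresp))
        inhale = phi[(dresp > 0) & strong]
        exhale = phi[(dresp < 0) & strong]
        assert np.all(inhale <= np.pi + 1e-9)
        assert np.all(exhale >= np.pi - 1e-9)

    def test_time_reversal_maps_to_complementary_branch(self):
        t = np.arange(0, 60, 0.01)
        resp = np.sin(0.6 * np.pi * t)
        rec_f = PhysioRecording(t, np.sin(2 * np.pi * t), resp, fs=100.0)
        rec_r = PhysioRecording(t, np.sin(2 * np.pi * t), resp[::-1], fs=100.0)
        q = np.arange(10, 50, 0.1)
        phi_f = respiratory_phase(rec_f, q)
        phi_r = respiratory_phase(rec_r, (t[-1] - q)[::-1])[::-1]
        # same amplitude but reversed slope sign: phases land on the mirror branch
        interior = (phi_f > 0.2) & (phi_f < 2 * np.pi - 0.2)
        np.testing.assert_allclose(
            phi_r[interior], (2 * np.pi - phi_f)[interior], atol=0.3
        )

    def test_constant_amplitude_rejected(self):
        rec = _rec(lambda t: np.sin(2 * np.pi * t), resp=np.ones(6000))
        with pytest.raises(ValueError, match="constant"):
            respiratory_phase(rec, np.array([10.0]))


class TestFourierBasis:
    @pytest.mark.parametrize(
        "phi,expected",
        [
            (0.0, (0, 1, 0, 1)),
            (np.pi / 2, (1, 0, 0, -1)),
            (np.pi / 4, (np.sqrt(2) / 2, np.sqrt(2) / 2, 1, 0)),
        ],
    )
    def test_reference_angles(self, phi, expected):
        np.testing.assert_allclose(fourier_basis(np.array(phi)), expected, atol=1e-12)

    def test_length_follows_harmonics(self):
        assert fourier_basis(np.zeros(3), n_harmonics=3).shape == (3, 6)


class TestSliceSampling:
    def test_perfect_gating_gives_constant_cardiac_columns(self):
        rec = _rec(lambda t: np.sin(2 * np.pi * t))
        peaks = np.arange(0.25, 59, 1.0)
        t = peaks[:20].reshape(10, 2) + 0.3  # every slice at the same phase
        timing = SliceTiming(t=t, slice_order=np.arange(2))
        phases = phase_at_slices(rec, timing, peak_times=peaks)
        regs = sample_at_slices(phases, timing)
        card = regs.values[..., :4]
        assert np.ptp(card, axis=0).max() < 1e-9
        assert regs.values.min() >= -1 and regs.values.max() <= 1

    def test_half_cycle_apart_slices_flip_sin_sign(self):
        rec = _rec(lambda t: np.sin(2 * np.pi * t))
        peaks = np.arange(0.25, 59, 1.0)
        t = np.array([[10.5, 11.0]])  # 0.5 cardiac cycles apart
        timing = SliceTiming(t=t, slice_order=np.arange(2))
        regs = sample_at_slices(phase_at_slices(rec, timing, peak_times=peaks), timing)
        sin_c = regs.values[0, :, 0]
        assert sin_c[0] * sin_c[1] < 0

    def test_export_frame_has_one_row_per_volume_slice(self):
        rec = _rec(lambda t: np.sin(2 * np.pi * t))
        peaks = np.arange(0.25, 59, 1.0)
        timing = SliceTiming(t=np.full((4, 3), 20.0) + np.arange(12).reshape(4, 3) * 0.1,
                             slice_order=np.arange(3))
        regs = sample_at_slices(phase_at_slices(rec, timing, peak_times=peaks), timing)
        frame = regs.to_frame()
        assert len(frame) == 12
        assert "cardiac_sin1" in frame.columns


class TestClosedLoop:
    def test_detection_recovers_true_beats_within_one_sample(self, physio_2min):
        rec, beats = physio_2min
        detected = detect_cardiac_peaks(rec)
        truth = beats[(beats >= detected[0] - 0.02) & (beats <= detected[-1] + 0.02)]
        assert detected.size == truth.size
        err = np.abs(detected - truth)
        assert err.max() <= 1.0 / rec.fs + 1e-9

    def test_phase_error_bounded_by_sampling(self, physio_2min):
        rec, beats = physio_2min
        detected = detect_cardiac_peaks(rec)
        q = np.arange(detected[0] + 1, detected[-1] - 1, 0.25)
        phi_det = cardiac_phase(detected, q)
        phi_true = cardiac_phase(beats, q)
        diff = np.abs(np.angle(np.exp(1j * (phi_det - phi_true))))
        # max error < 2*pi * (1/fs) / min inter-beat interval
        bound = 2 * np.pi * (1.0 / rec.fs) / np.diff(beats).min()
        assert diff.max() < bound + 1e-9
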