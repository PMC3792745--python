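"""Cardiac/respiratory phase estimation and Fourier regressor construction.

Peripheral recordings are turned into slice-time-resolved phases in the
RETROICOR fashion: the cardiac phase advances linearly from 0 to 2*pi
between successive pulse-oximeter peaks, and the respiratory phase is the
histogram-equalized belt amplitude signed by the derivative (inhale vs
exhale).  Regressors are sine/cosine Fourier terms of those phases up to
the second harmonic, evaluated at the true acquisition time of every
(volume, slice) pair, so the nuisance design changes from slice to slice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.signal import butter, filtfilt, find_peaks

from .io import PhysioRecording, SliceTiming

__all__ = [
    "PhaseSeries",
    "RegressorSet",
    "detect_cardiac_peaks",
    "cardiac_phase",
    "respiratory_phase",
    "fourier_basis",
    "phase_at_slices",
    "sample_at_slices",
]

TWO_PI = 2.0 * np.pi

#: physiologic inter-beat interval range (s) used for beat cleaning
MIN_IBI, MAX_IBI = 0.33, 2.0


@dataclass
class PhaseSeries:
    """Cardiac and respiratory phase (radians, [0, 2*pi)) at times t."""

    t: np.ndarray
    phi_c: np.ndarray
    phi_r: np.ndarray


@dataclass
class RegressorSet:
    """Fourier basis evaluations per (volume, slice); values in [-1, 1]."""

    values: np.ndarray  # (n_volumes, n_slices, n_basis)
    labels: list

    def to_frame(self) -> pd.DataFrame:
        """Audit export: one row per volume x slice, labeled columns."""
        n_vol, n_slc, _ = self.values.shape
        vol, slc = np.meshgrid(np.arange(n_vol), np.arange(n_slc), indexing="ij")
        frame = pd.DataFrame({"volume": vol.ravel(), "slice": slc.ravel()})
        for k, label in enumerate(self.labels):
            frame[label] = self.values[..., k].ravel()
        return frame


def detect_cardiac_peaks(rec: PhysioRecording) -> np.ndarray:
    """Beat times from the pulse-oximeter channel.

    Band-pass 0.5-3 Hz, local maxima with minimum separation 0.33 s and
    prominence >= 0.3x the robust (MAD-based) amplitude, then each peak is
    refined to the raw-signal maximum within +-0.15 s so the returned times
    land on the sample closest to the true systolic peak.
    """
    x = rec.cardiac
    if rec.duration < 10.0:
        raise ValueError("cardiac trace shorter than 10 s")
    robust_amp = 1.4826 * np.median(np.abs(x - np.median(x)))
    if robust_amp <= 0:
        raise ValueError("cardiac channel is flat")
    nyq = rec.fs / 2.0
    b, a = butter(3, [0.5 / nyq, min(3.0 / nyq, 0.99)], btype="band")
    xf = filtfilt(b, a, x)
    idx, _ = find_peaks(
        xf, distance=max(1, int(round(MIN_IBI * rec.fs))), prominence=0.3 * robust_amp
    )
    # refine on the unfiltered trace (the filter can skew asymmetric pulses)
    half = int(round(0.15 * rec.fs))
    refined = []
    for i in idx:
        lo, hi = max(0, i - half), min(x.size, i + half + 1)
        refined.append(lo + int(np.argmax(x[lo:hi])))
    idx = np.unique(refined)
    times = rec.time[idx]
    # drop beats implying a non-physiologic short interval
    keep = [0]
    for k in range(1, times.size):
        if times[k] - times[keep[-1]] >= MIN_IBI:
            keep.append(k)
    times = times[keep]
    if times.size < 2:
        raise ValueError(f"found only {times.size} cardiac peak(s)")
    return times


def flag_ectopic_intervals(peak_times: np.ndarray) -> np.ndarray:
    """Boolean flags for inter-beat intervals outside [0.33, 2.0] s."""
    ibi = np.diff(peak_times)
    return (ibi < MIN_IBI) | (ibi > MAX_IBI)


def cardiac_phase(peak_times: np.ndarray, query_times: np.ndarray) -> np.ndarray:
    """Linear cardiac phase: 0 at each beat, advancing to 2*pi at the next.

    Query times must lie within [first_peak, last_peak]; extrapolation is a
    hard error (silently extrapolated phases corrupt the regressors).
    """
    peaks = np.asarray(peak_times, dtype=float)
    t = np.asarray(query_times, dtype=float)
    outside = (t < peaks[0]) | (t > peaks[-1])
    if np.any(outside):
        bad = np.asarray(t)[outside].ravel()[:10]
        raise ValueError(
            f"query time(s) outside the detected beat span "
            f"[{peaks[0]:.3f}, {peaks[-1]:.3f}] s: {np.round(bad, 3).tolist()}"
        )
    k = np.clip(np.searchsorted(peaks, t, side="right") - 1, 0, peaks.size - 2)
    phase = TWO_PI * (t - peaks[k]) / (peaks[k + 1] - peaks[k])
    return np.mod(phase, TWO_PI)


def respiratory_phase(
    rec: PhysioRecording, query_times: np.ndarray, n_bins: int = 100
) -> np.ndarray:
    """Histogram-equalized respiratory phase in [0, 2*pi).

    phi_r = pi * H(|a|) * sign(da/dt) mapped to [0, 2*pi), with a the
    detrended belt amplitude, H the normalized cumulative histogram of |a|
    (``n_bins`` equal-width bins) and the derivative taken by centered
    differences smoothed over 1 s.  Inhalation (rising amplitude) maps to
    [0, pi], exhalation to (pi, 2*pi).
    """
    a = rec.respiratory - np.mean(rec.respiratory)
    if np.ptp(a) <= 0:
        raise ValueError("respiratory channel has constant amplitude")
    win = max(1, int(round(rec.fs)))
    da = uniform_filter1d(np.gradient(a, rec.time), size=win)

    mag = np.abs(a)
    hist, edges = np.histogram(mag, bins=n_bins, range=(0.0, mag.max()))
    cum = np.concatenate([[0.0], np.cumsum(hist)]) / mag.size

    t = np.asarray(query_times, dtype=float)
    if np.any((t < rec.time[0]) | (t > rec.time[-1])):
        raise ValueError("query time(s) outside the respiratory recording span")
    a_q = np.interp(t, rec.time, a)
    da_q = np.interp(t, rec.time, da)
    h_q = np.interp(np.abs(a_q), edges, cum)
    sign = np.where(da_q >= 0, 1.0, -1.0)
    return np.mod(np.pi * h_q * sign, TWO_PI)


def fourier_basis(phi: np.ndarray, n_harmonics: int = 2) -> np.ndarray:
    """(sin phi, cos phi, sin 2*phi, cos 2*phi, ...) stacked on the last axis."""
    phi = np.asarray(phi, dtype=float)
    parts = []
    for h in range(1, n_harmonics + 1):
        parts.append(np.sin(h * phi))
        parts.append(np.cos(h * phi))
    return np.stack(parts, axis=-1)


def basis_labels(prefix: str, n_harmonics: int = 2) -> list:
    labels = []
    for h in range(1, n_harmonics + 1):
        labels += [f"{prefix}_sin{h}", f"{prefix}_cos{h}"]
    return labels


def phase_at_slices(
    rec: PhysioRecording,
    timing: SliceTiming,
    peak_times: np.ndarray | None = None,
) -> PhaseSeries:
    """Cardiac and respiratory phases at every (volume, slice) time.

    ``peak_times`` may be supplied (e.g. simulator ground truth or an
    external trigger log); otherwise beats are detected from the cardiac
    channel.
    """
    if peak_times is None:
        peak_times = detect_cardiac_peaks(rec)
    t = timing.t
    phi_c = cardiac_phase(peak_times, t.ravel()).reshape(t.shape)
    phi_r = respiratory_phase(rec, t.ravel()).reshape(t.shape)
    return PhaseSeries(t=t, phi_c=phi_c, phi_r=phi_r)


def sample_at_slices(
    phase: PhaseSeries, timing: SliceTiming, n_harmonics: int = 2
) -> RegressorSet:
    """Evaluate the Fourier bases of both phases at every slice time."""
    if phase.t.shape != timing.t.shape or not np.allclose(phase.t, timing.t):
        raise ValueError("phase series was not evaluated at this slice timing")
    card = fourier_basis(phase.phi_c, n_harmonics)
    resp = fourier_basis(phase.phi_r, n_harmonics)
    values = np.concatenate([card, resp], axis=-1)
    labels = basis_labels("cardiac", n_harmonics) + basis_labels("resp", n_harmonics)
    return RegressorSet(values=values, labels=labels)
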