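"""Synthetic DWI + physiology generator with known ground truth.

The forward model is the diffusion signal equation multiplied by a
time-dependent physiological perturbation and degraded by Rician
measurement noise::

    S = S0 * exp(-b * g^T D g)                 (diffusion attenuation)
        * (1 + sum_k p_k q_k(t))               (small linear modulation)
        * (1 - dropout(phi_c, |g_z|, voxel))   (cardiac-locked signal loss)
        -> Rician(S, sigma = S0 / SNR)

The linear modulation follows the cardiac/respiratory Fourier phases
evaluated at the true slice acquisition times; the dropout term acts only
during a systolic cardiac-phase window, only on high-|g_z| directions
(scaled by the same gated-Gaussian apodization weight the correction model
uses), and only inside a basal slab of the phantom — emulating
pulsation-induced k-space-shift signal loss in the lower brain.

Acquisition timing mirrors the two study modes: a free-running ("nongated")
interleaved acquisition with a fixed volume TR of 8.5 s, and a cardiac
gated acquisition placing blocks of three slices at a fixed diastolic delay
after each detected beat (variable volume TR, ~17 s at 1 Hz and 50
slices).  The gradient scheme is 60 spherically spread directions at
b = 700 s/mm^2 plus six interleaved low-DW volumes at b = 100 s/mm^2.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .design import apodization_weight
from .io import GradientScheme, PhysioRecording, SliceTiming, VolumeSeries
from .physio import cardiac_phase, fourier_basis, respiratory_phase
from .tensor import design_row, fa_from_vec

__all__ = [
    "PhantomSpec",
    "PerturbationSpec",
    "SimulatedDataset",
    "make_scheme",
    "repulsion_energy",
    "simulate_physio",
    "simulate_timing",
    "simulate_dwi",
]

TWO_PI = 2.0 * np.pi

#: rod tensor: prolate, principal axis x, FA ~ 0.870
ROD_TENSOR = np.array([1.7e-3, 0.2e-3, 0.2e-3, 0.0, 0.0, 0.0])
#: isotropic background tensor, FA = 0
BACKGROUND_TENSOR = np.array([0.7e-3, 0.7e-3, 0.7e-3, 0.0, 0.0, 0.0])


# ---------------------------------------------------------------------------
# phantom


@dataclass
class PhantomSpec:
    """Desk-scale phantom: anisotropic rod in an isotropic background.

    The rod is a cylinder along x (radius ``rod_radius`` voxels around
    (rod_cy, rod_cz)); the ``n_basal_slices`` lowest slices form the
    "basal" slab where pulsation-locked dropout acts.
    """

    shape: tuple = (32, 32, 12)
    d_rod: np.ndarray = field(default_factory=lambda: ROD_TENSOR.copy())
    d_background: np.ndarray = field(default_factory=lambda: BACKGROUND_TENSOR.copy())
    rod_cy: float = 16.0
    rod_cz: float = 6.0
    rod_radius: float = 4.0
    s0: float = 1000.0
    n_basal_slices: int = 4

    def rod_mask(self) -> np.ndarray:
        _, ny, nz = self.shape
        y, z = np.meshgrid(np.arange(ny), np.arange(nz), indexing="ij")
        disc = (y - self.rod_cy) ** 2 + (z - self.rod_cz) ** 2 <= self.rod_radius**2
        return np.broadcast_to(disc[None, :, :], self.shape).copy()

    def basal_mask(self) -> np.ndarray:
        mask = np.zeros(self.shape, dtype=bool)
        mask[:, :, : self.n_basal_slices] = True
        return mask

    def tensor_field(self) -> np.ndarray:
        d = np.empty(self.shape + (6,))
        d[:] = self.d_background
        d[self.rod_mask()] = self.d_rod
        return d


# ---------------------------------------------------------------------------
# gradient scheme


def repulsion_energy(points: np.ndarray) -> float:
    """Coulomb energy sum 1/|x_i - x_j| over unit-sphere point pairs."""
    diff = points[:, None, :] - points[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    iu = np.triu_indices(points.shape[0], k=1)
    return float(np.sum(1.0 / dist[iu]))


def _repel(points: np.ndarray, n_iter: int = 600, step: float = 5e-3) -> np.ndarray:
    """Gradient descent on the Coulomb energy, points constrained to the sphere."""
    x = points / np.linalg.norm(points, axis=1, keepdims=True)
    for _ in range(n_iter):
        diff = x[:, None, :] - x[None, :, :]
        dist = np.linalg.norm(diff, axis=-1)
        np.fill_diagonal(dist, np.inf)
        force = np.sum(diff / dist[..., None] ** 3, axis=1)
        # project onto the tangent plane, then renormalize
        force -= np.sum(force * x, axis=1, keepdims=True) * x
        x = x + step * force
        x /= np.linalg.norm(x, axis=1, keepdims=True)
    return x


_OCTAHEDRON = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]], dtype=float
)


def make_scheme(
    n_dirs: int = 60,
    b_high: float = 700.0,
    n_low: int = 6,
    b_low: float = 100.0,
    seed: int = 0,
) -> GradientScheme:
    """Two-shell scheme: spherically spread high-b directions + low-b volumes.

    High-b directions come from electrostatic repulsion started from a
    seeded random configuration (``n_dirs = 6`` returns the exact
    octahedron, the known optimum).  The ``n_low`` low-b volumes are
    interleaved evenly; with ``b_low = 0`` they are direction-free
    (g = 0) reference volumes, otherwise they cycle through the coordinate
    axes.
    """
    if n_dirs < 6:
        raise ValueError("need at least 6 diffusion directions")
    if n_dirs == 6:
        g_high = _OCTAHEDRON.copy()
    else:
        rng = np.random.default_rng(seed)
        g_high = _repel(rng.normal(size=(n_dirs, 3)))

    n_total = n_dirs + n_low
    low_idx = np.round(np.linspace(0, n_total, n_low, endpoint=False)).astype(int)
    b = np.full(n_total, b_high)
    g = np.zeros((n_total, 3))
    axes = np.eye(3)
    hi = 0
    for i in range(n_total):
        if i in low_idx:
            b[i] = b_low
            g[i] = 0.0 if b_low == 0 else axes[int(np.where(low_idx == i)[0][0]) % 3]
        else:
            g[i] = g_high[hi]
            hi += 1
    return GradientScheme(b=b, g=g)


# ---------------------------------------------------------------------------
# physiology


def simulate_physio(
    duration_s: float,
    heart_rate_hz: float = 1.0,
    hr_std: float = 0.07,
    resp_rate_hz: float = 0.3,
    fs: float = 100.0,
    seed: int = 0,
    pre_roll_s: float = 10.0,
    noise_amp: float = 0.01,
) -> tuple[PhysioRecording, np.ndarray]:
    """Quasi-periodic pulse and breathing traces; returns (recording, beat times).

    Beat intervals are Gaussian around 1/heart_rate (clipped to
    [0.7, 1.5]/heart_rate) and quantized to the sampling grid, so the
    systolic waveform peak of every beat falls exactly on a sample; the
    true beat times are returned as ground truth.  The recording starts
    ``pre_roll_s`` before time zero (the first slice trigger), as a
    scan-locked peripheral recording would.
    """
    rng = np.random.default_rng(seed)
    t0 = -float(pre_roll_s)
    time = t0 + np.arange(int(round((duration_s - t0) * fs)) + 1) / fs

    mean_ibi = 1.0 / heart_rate_hz
    n_beats = int(math.ceil((duration_s - t0) / (0.7 * mean_ibi))) + 4
    ibi = np.clip(rng.normal(mean_ibi, hr_std, size=n_beats), 0.7 * mean_ibi, 1.5 * mean_ibi)
    beats = t0 + 0.5 * mean_ibi + np.cumsum(np.concatenate([[0.0], ibi]))
    beats = np.round(beats * fs) / fs  # quantize to the sampling grid
    beats = beats[beats <= time[-1] - 0.3]

    cardiac = np.zeros_like(time)
    for tb in beats:
        lo = np.searchsorted(time, tb - 0.6)
        hi = np.searchsorted(time, tb + 0.8)
        tt = time[lo:hi] - tb
        cardiac[lo:hi] += np.exp(-(tt**2) / (2 * 0.08**2))  # systolic peak
        cardiac[lo:hi] += 0.2 * np.exp(-((tt - 0.25) ** 2) / (2 * 0.12**2))  # dicrotic
    cardiac += noise_amp * rng.normal(size=time.size)

    # breathing: frequency-modulated sinusoid (slow random drift of the rate)
    drift = rng.normal(size=time.size)
    kernel = np.exp(-0.5 * (np.arange(-500, 501) / 150.0) ** 2)
    drift = np.convolve(drift, kernel / kernel.sum(), mode="same")
    drift /= max(np.std(drift), 1e-12)
    f_inst = resp_rate_hz * (1.0 + 0.08 * drift)
    psi = TWO_PI * np.cumsum(f_inst) / fs
    respiratory = np.sin(psi) + noise_amp * rng.normal(size=time.size)

    rec = PhysioRecording(time=time, cardiac=cardiac, respiratory=respiratory, fs=fs)
    return rec, beats


# ---------------------------------------------------------------------------
# slice timing


def simulate_timing(
    mode: str,
    n_volumes: int,
    n_slices: int = 12,
    tr_nongated: float = 8.5,
    beat_times: np.ndarray | None = None,
    block_size: int = 3,
    trigger_delay: float = 0.5,
    slice_gap: float = 0.08,
) -> SliceTiming:
    """Slice acquisition times for the nongated or gated mode.

    nongated: interleaved order (even slices, then odd), evenly spaced over
    the fixed volume TR.  gated: blocks of ``block_size`` adjacent slices
    placed at a fixed diastolic ``trigger_delay`` after consecutive beats
    (one cardiac cycle per block), giving a variable volume TR.
    """
    if mode == "nongated":
        order = np.concatenate([np.arange(0, n_slices, 2), np.arange(1, n_slices, 2)])
        position = np.empty(n_slices, dtype=int)
        position[order] = np.arange(n_slices)
        t = (
            np.arange(n_volumes)[:, None] * tr_nongated
            + position[None, :] * (tr_nongated / n_slices)
        )
        return SliceTiming(t=t, slice_order=order)
    if mode != "gated":
        raise ValueError(f"unknown timing mode {mode!r}")

    if beat_times is None:
        raise ValueError("gated timing requires beat times")
    beats = np.asarray(beat_times, dtype=float)
    beats = beats[beats >= 0.0]
    n_blocks = int(math.ceil(n_slices / block_size))
    if beats.size < n_volumes * n_blocks + 1:
        raise ValueError(
            f"physio recording too short: need {n_volumes * n_blocks + 1} beats "
            f"after t=0, have {beats.size}"
        )
    t = np.empty((n_volumes, n_slices))
    k = 0
    for i in range(n_volumes):
        for blk in range(n_blocks):
            for j in range(block_size):
                s = blk * block_size + j
                if s < n_slices:
                    t[i, s] = beats[k] + trigger_delay + j * slice_gap
            k += 1
    return SliceTiming(t=t, slice_order=np.argsort(t[0], kind="stable"))


# ---------------------------------------------------------------------------
# perturbation and forward model


@dataclass
class PerturbationSpec:
    """Physiological perturbation of the DW signal.

    ``cardiac_lin`` / ``resp_lin`` weight the (sin, cos, sin2, cos2)
    Fourier terms of the respective phase as fractional signal modulation
    (0.05 = 5%).  ``dropout_amplitude`` is the maximal fractional signal
    loss in systole for fully gated-out (|g_z| = q0) directions, applied
    inside the basal slab only; the amplitude is shaped by the same
    apodization weight A(g_z) the correction model uses unless
    ``dropout_apod_width`` overrides the width (model-misspecification
    stress variant).  ``domain`` selects the multiplicative form:
    "signal" applies (1 + f); "log" applies exp(f), i.e. a perturbation
    exactly within the span of the linearized extended model.
    """

    cardiac_lin: np.ndarray = field(default_factory=lambda: np.array([0.05, 0.0, 0.0, 0.0]))
    resp_lin: np.ndarray = field(default_factory=lambda: np.array([0.02, 0.0, 0.0, 0.0]))
    dropout_amplitude: float = 0.5
    systole_window: tuple = (0.0, np.pi / 2)
    q0: float = 0.5
    apod_width: float = 0.5
    dropout_apod_width: float | None = None
    domain: str = "signal"
    #: whether the linear modulation also multiplies the low-DW reference
    #: volumes (physically it does; the extended model cannot absorb the
    #: resulting per-voxel reference shift, see docs/methods.md)
    perturb_reference: bool = True

    @classmethod
    def none(cls) -> "PerturbationSpec":
        return cls(
            cardiac_lin=np.zeros(4), resp_lin=np.zeros(4), dropout_amplitude=0.0
        )

    def __post_init__(self) -> None:
        self.cardiac_lin = np.asarray(self.cardiac_lin, dtype=float)
        self.resp_lin = np.asarray(self.resp_lin, dtype=float)
        if self.domain not in ("signal", "log"):
            raise ValueError(f"unknown perturbation domain {self.domain!r}")
        if not (0.0 <= self.dropout_amplitude < 1.0):
            raise ValueError("dropout amplitude must be in [0, 1)")


@dataclass
class SimulatedDataset:
    """A complete synthetic acquisition with its generating ground truth."""

    series: VolumeSeries
    scheme: GradientScheme
    physio: PhysioRecording
    timing: SliceTiming
    truth: dict


def simulate_dwi(
    phantom: PhantomSpec,
    scheme: GradientScheme,
    timing: SliceTiming,
    physio: PhysioRecording,
    beat_times: np.ndarray,
    pert: PerturbationSpec,
    snr: float | None = 40.0,
    seed: int = 0,
) -> SimulatedDataset:
    """Run the forward model and bundle data + ground truth.

    ``snr`` is S0 over the Gaussian noise SD of each quadrature channel
    before magnitude formation (standard Rician construction); ``None`` or
    ``inf`` disables measurement noise.
    """
    nx, ny, nz = phantom.shape
    n_vol = scheme.n_volumes
    if timing.n_volumes != n_vol:
        raise ValueError("timing and scheme disagree on the number of volumes")
    if timing.n_slices != nz:
        raise ValueError(f"timing has {timing.n_slices} slices, phantom has {nz}")

    d_field = phantom.tensor_field()
    rows = design_row(scheme.g)  # (n_vol, 6)
    adc_true = np.einsum("xyzp,vp->xyzv", d_field, rows)
    s_clean = phantom.s0 * np.exp(-scheme.b[None, None, None, :] * adc_true)

    # linear modulation f(volume, slice)
    phi_c = cardiac_phase(beat_times, timing.t.ravel()).reshape(timing.t.shape)
    phi_r = respiratory_phase(physio, timing.t.ravel()).reshape(timing.t.shape)
    f = fourier_basis(phi_c, 2) @ pert.cardiac_lin + fourier_basis(phi_r, 2) @ pert.resp_lin

    if pert.domain == "signal":
        if np.any(1.0 + f <= 0):
            raise ValueError("linear perturbation drives the signal non-positive")
        lin_factor = 1.0 + f
    else:
        lin_factor = np.exp(f)
    if not pert.perturb_reference:
        lin_factor = np.where(scheme.is_high[:, None], lin_factor, 1.0)

    # cardiac-locked dropout on high-|g_z| directions, basal slab only;
    # the loss scales with the diffusion-gradient amplitude, so the weak
    # low-DW gradients are exempt
    width = pert.dropout_apod_width if pert.dropout_apod_width is not None else pert.apod_width
    a_gz = apodization_weight(scheme.g[:, 2], q0=pert.q0, apod_width=width)  # (n_vol,)
    a_gz = np.where(scheme.is_high, a_gz, 0.0)
    lo, hi = pert.systole_window
    in_window = (phi_c >= lo) & (phi_c < hi)  # (n_vol, n_slices)
    basal_slice = np.zeros(nz, dtype=bool)
    basal_slice[: phantom.n_basal_slices] = True
    drop = pert.dropout_amplitude * a_gz[None, :] * in_window.T  # (n_slices, n_vol)
    drop = drop * basal_slice[:, None]

    # combine: S(x, y, z, v) = s_clean * lin_factor(v, z) * (1 - drop(z, v))
    factor = lin_factor.T * (1.0 - drop)  # (n_slices, n_vol)
    signal = s_clean * factor[None, None, :, :]
    if np.any(signal <= 0):
        raise ValueError("perturbation drives the signal non-positive")

    if snr is not None and np.isfinite(snr):
        rng = np.random.default_rng(seed)
        sigma = phantom.s0 / snr
        n1 = rng.normal(scale=sigma, size=signal.shape)
        n2 = rng.normal(scale=sigma, size=signal.shape)
        signal = np.sqrt((signal + n1) ** 2 + n2**2)

    series = VolumeSeries(data=signal, affine=np.diag([2.7, 2.7, 2.7, 1.0]))
    truth = {
        "tensor": d_field,
        "fa": fa_from_vec(d_field),
        "rod_mask": phantom.rod_mask(),
        "basal_mask": phantom.basal_mask(),
        "beat_times": beat_times,
        "phi_c": phi_c,
        "phi_r": phi_r,
        "lin_modulation": f,
        "dropout": drop,  # (n_slices, n_volumes) fractional loss per direction gate
        "dropout_gate": a_gz,
        "phantom": phantom,
        "perturbation": pert,
        "snr": snr,
        "seed": seed,
    }
    return SimulatedDataset(
        series=series, scheme=scheme, physio=physio, timing=timing, truth=truth
    )
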