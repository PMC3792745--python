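"""The study-condition scenario battery.

Each scenario fixes one mechanism of the physiological-noise problem on the
default desk-scale phantom (anisotropic rod, FA ~ 0.87, in an isotropic
background, lowest four slices forming the pulsation-affected basal slab):

* ``identity`` — no perturbation, no measurement noise, b = 0 reference
  shell: the forward-inverse identity of the standard tensor fit.
* ``linear_recovery`` — 5% cardiac-locked modulation exactly within the
  span of the linearized extended model (log domain), no measurement
  noise: exact parameter recovery by the linear-cardiac model, biased
  standard fit.
* ``nongated_outlier`` — free-running timing, full physical perturbation
  (5% cardiac + 2% respiratory modulation, 50% cardiac-locked dropout on
  high-|g_z| directions in the basal slab) at SNR 20: the outlier-rich
  regime where robust fitting shines.
* ``gated_linear`` — cardiac-gated timing with a diastolic trigger delay
  (the systolic dropout window is never hit), cardiac-only 5% modulation,
  no measurement noise: the residual small-amplitude regime where the
  linear-regressor models shine; see docs/methods.md for why this scenario
  excludes respiratory modulation and thermal noise.

All scenarios are deterministic under a fixed seed.
"""

from __future__ import annotations

import numpy as np

from .simulate import (
    PerturbationSpec,
    PhantomSpec,
    SimulatedDataset,
    make_scheme,
    simulate_dwi,
    simulate_physio,
    simulate_timing,
)

__all__ = [
    "build_dataset",
    "scenario_identity",
    "scenario_linear_recovery",
    "scenario_nongated_outlier",
    "scenario_gated_linear",
]

N_VOLUMES = 66  # 60 DW + 6 low-DW


def build_dataset(
    mode: str = "nongated",
    pert: PerturbationSpec | None = None,
    snr: float | None = 40.0,
    seed: int = 0,
    phantom: PhantomSpec | None = None,
    b_low: float = 100.0,
    n_dirs: int = 60,
    n_low: int = 6,
) -> SimulatedDataset:
    """Assemble scheme, physiology, timing and signal for one scenario."""
    phantom = phantom if phantom is not None else PhantomSpec()
    pert = pert if pert is not None else PerturbationSpec()
    scheme = make_scheme(n_dirs=n_dirs, n_low=n_low, b_low=b_low, seed=seed)
    n_vol = scheme.n_volumes
    nz = phantom.shape[2]
    if mode == "nongated":
        duration = n_vol * 8.5 + 5.0
    else:
        blocks = -(-nz // 3)
        duration = n_vol * blocks * 1.6 + 10.0  # worst-case long beats
    physio, beats = simulate_physio(duration_s=duration, seed=seed + 1)
    timing = simulate_timing(mode, n_volumes=n_vol, n_slices=nz, beat_times=beats)
    return simulate_dwi(
        phantom, scheme, timing, physio, beats, pert, snr=snr, seed=seed + 2
    )


def scenario_identity(seed: int = 0) -> SimulatedDataset:
    """Noiseless, unperturbed acquisition with an exact b=0 reference shell."""
    return build_dataset(
        mode="nongated", pert=PerturbationSpec.none(), snr=None, seed=seed, b_low=0.0
    )


def scenario_linear_recovery(seed: int = 0) -> SimulatedDataset:
    """5% cardiac modulation within the linear model span, no noise."""
    pert = PerturbationSpec(
        cardiac_lin=np.array([0.05, 0.0, 0.0, 0.0]),
        resp_lin=np.zeros(4),
        dropout_amplitude=0.0,
        domain="log",
        perturb_reference=False,
    )
    return build_dataset(mode="nongated", pert=pert, snr=None, seed=seed, b_low=0.0)


def scenario_nongated_outlier(seed: int = 0) -> SimulatedDataset:
    """Outlier-rich free-running acquisition at SNR 20 (full default perturbation)."""
    return build_dataset(mode="nongated", pert=PerturbationSpec(), snr=20.0, seed=seed)


def scenario_gated_linear(seed: int = 0) -> SimulatedDataset:
    """Gated acquisition leaving only small cardiac-locked linear modulation."""
    pert = PerturbationSpec(
        cardiac_lin=np.array([0.05, 0.0, 0.0, 0.0]),
        resp_lin=np.zeros(4),
        dropout_amplitude=0.5,  # present but never triggered: diastolic trigger
    )
    return build_dataset(mode="gated", pert=pert, snr=None, seed=seed)
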