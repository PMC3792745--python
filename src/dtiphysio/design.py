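"""Noise-regressor (Q) matrices and the extended tensor design [X | Q].

The extended tensor model augments the standard per-voxel linear model
``adc = X d`` with ``m`` physiological noise regressors,
``adc = [X | Q] (d, p)``, so that multiplicative signal perturbations are
absorbed by the ``p`` weights instead of biasing the tensor ``d``.

Two regressor families are provided:

* linear — Fourier terms of the cardiac/respiratory phase divided by the
  effective b (the log-linearization ln(1+f) ~ f moves an additive signal
  term into the ADC domain with a 1/b scale);
* nonlinear — first-harmonic cardiac terms apodized by
  ``A(g_z) = Theta(|g_z| - q0) * exp(-((|g_z| - q0)/sigma_A)^2)``, modeling
  pulsation-induced k-space shifts interacting with the reconstruction
  apodization, which suppress signal preferentially on high-|g_z|
  directions.  No cross-terms between regressors are formed (they would
  inflate the condition number of the extended design).

The model family (model ids, regressor counts) is:

========================  ==================================  ==  =====
id                        noise regressors                     m  6 + m
========================  ==================================  ==  =====
standard                  none                                 0      6
lin_cardiac               linear cardiac (2 harmonics)         4     10
lin_cardiac_resp          linear cardiac + respiratory         8     14
nonlin_cardiac            apodized cardiac (1st harmonic)      2      8
nonlin_cardiac_lin_resp   linear respiratory + apodized card.  6     12
robust                    none (outlier down-weighting)        0      6
========================  ==================================  ==  =====
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import GradientScheme
from .physio import RegressorSet, basis_labels

__all__ = [
    "MODEL_IDS",
    "ROMAN",
    "ModelSpec",
    "NoiseRegressorMatrix",
    "apodization_weight",
    "build_linear_Q",
    "build_nonlinear_Q",
    "build_Q",
    "assemble_extended_design",
]

MODEL_IDS = (
    "standard",
    "lin_cardiac",
    "lin_cardiac_resp",
    "nonlin_cardiac",
    "nonlin_cardiac_lin_resp",
    "robust",
)

#: conventional roman-numeral labels of the model family
ROMAN = {
    "standard": "(i)",
    "lin_cardiac": "(ii)",
    "lin_cardiac_resp": "(iii)",
    "nonlin_cardiac": "(iv)",
    "nonlin_cardiac_lin_resp": "(v)",
    "robust": "(vi)",
}

_M_COUNT = {
    "standard": 0,
    "lin_cardiac": 4,
    "lin_cardiac_resp": 8,
    "nonlin_cardiac": 2,
    "nonlin_cardiac_lin_resp": 6,
    "robust": 0,
}


@dataclass
class ModelSpec:
    """One member of the model family, with its apodization parameters."""

    model_id: str
    q0: float = 0.5
    apod_width: float = 0.5
    n_harmonics: int = 2

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"unknown model id {self.model_id!r}; valid: {MODEL_IDS}")

    @property
    def m(self) -> int:
        return _M_COUNT[self.model_id]

    @property
    def p_total(self) -> int:
        return 6 + self.m

    @property
    def is_robust(self) -> bool:
        return self.model_id == "robust"

    @property
    def needs_physio(self) -> bool:
        return self.m > 0

    @property
    def roman(self) -> str:
        return ROMAN[self.model_id]


@dataclass
class NoiseRegressorMatrix:
    """N x m noise-regressor block for one slice, in ADC units after 1/b."""

    Q: np.ndarray
    labels: list

    @property
    def m(self) -> int:
        return self.Q.shape[1]


def apodization_weight(g_z, q0: float = 0.5, apod_width: float = 0.5) -> np.ndarray:
    """Gated Gaussian apodization weight A(g_z) in [0, 1].

    A = Theta(|g_z| - q0) * exp(-((|g_z| - q0)/apod_width)^2), with
    Theta(0) = 1.  q0 = 0.5 gives good detection of pulsation artifacts for
    typical reconstructions; it is reconstruction-dependent.
    """
    mag = np.abs(np.asarray(g_z, dtype=float))
    gate = mag >= q0
    return np.where(gate, np.exp(-(((mag - q0) / apod_width) ** 2)), 0.0)


def _slice_samples(regs: RegressorSet, scheme: GradientScheme, slice_index: int):
    values = regs.values[:, slice_index, :]
    if values.shape[0] != scheme.n_volumes:
        raise ValueError(
            f"regressor set covers {values.shape[0]} volumes, scheme has {scheme.n_volumes}"
        )
    if not np.all(np.isfinite(values)):
        raise ValueError(f"missing regressor sample(s) at slice {slice_index}")
    high = scheme.high_indices()
    b_eff = scheme.b[high] - scheme.b_low
    return values[high], b_eff, high


def build_linear_Q(
    regs: RegressorSet,
    scheme: GradientScheme,
    slice_index: int,
    include: tuple = ("cardiac", "resp"),
    n_harmonics: int = 2,
) -> NoiseRegressorMatrix:
    """Linear noise regressors: Fourier samples divided by b_eff per volume."""
    values, b_eff, _ = _slice_samples(regs, scheme, slice_index)
    cols, labels = [], []
    for prefix in include:
        wanted = basis_labels(prefix, n_harmonics)
        idx = [regs.labels.index(w) for w in wanted]
        cols.append(values[:, idx])
        labels += wanted
    Q = np.concatenate(cols, axis=1) / b_eff[:, None]
    _warn_if_degenerate(Q, labels)
    return NoiseRegressorMatrix(Q=Q, labels=labels)


def build_nonlinear_Q(
    regs: RegressorSet,
    scheme: GradientScheme,
    slice_index: int,
    q0: float = 0.5,
    apod_width: float = 0.5,
) -> NoiseRegressorMatrix:
    """Apodized cardiac regressors: A(g_z) * (sin, cos) of cardiac phase / b_eff.

    If no direction passes the |g_z| >= q0 gate the columns are retained as
    zeros with a warning, and the model degenerates gracefully.
    """
    values, b_eff, high = _slice_samples(regs, scheme, slice_index)
    sin_c = values[:, regs.labels.index("cardiac_sin1")]
    cos_c = values[:, regs.labels.index("cardiac_cos1")]
    A = apodization_weight(scheme.g[high, 2], q0=q0, apod_width=apod_width)
    if not np.any(A > 0):
        warnings.warn(
            f"no diffusion direction passes the |g_z| >= {q0} apodization gate; "
            "nonlinear regressor columns are all zero",
            stacklevel=2,
        )
    Q = np.stack([A * sin_c, A * cos_c], axis=1) / b_eff[:, None]
    return NoiseRegressorMatrix(Q=Q, labels=["apod_cardiac_sin1", "apod_cardiac_cos1"])


def build_Q(
    spec: ModelSpec, regs: RegressorSet, scheme: GradientScheme, slice_index: int
) -> NoiseRegressorMatrix:
    """Assemble the Q block of one slice for any member of the model family."""
    if spec.m == 0:
        n = int(scheme.is_high.sum())
        return NoiseRegressorMatrix(Q=np.empty((n, 0)), labels=[])
    if spec.model_id == "lin_cardiac":
        return build_linear_Q(regs, scheme, slice_index, include=("cardiac",))
    if spec.model_id == "lin_cardiac_resp":
        return build_linear_Q(regs, scheme, slice_index, include=("cardiac", "resp"))
    if spec.model_id == "nonlin_cardiac":
        return build_nonlinear_Q(regs, scheme, slice_index, spec.q0, spec.apod_width)
    # (v): linear respiratory + apodized cardiac
    lin = build_linear_Q(regs, scheme, slice_index, include=("resp",))
    non = build_nonlinear_Q(regs, scheme, slice_index, spec.q0, spec.apod_width)
    return NoiseRegressorMatrix(
        Q=np.concatenate([lin.Q, non.Q], axis=1), labels=lin.labels + non.labels
    )


def _warn_if_degenerate(Q: np.ndarray, labels: list) -> None:
    const = np.ptp(Q, axis=0) < 1e-12 * (np.max(np.abs(Q), axis=0) + 1e-300)
    if np.any(const):
        bad = [labels[i] for i in np.where(const)[0]]
        warnings.warn(
            f"noise regressor column(s) {bad} are constant across volumes; "
            "the extended design will be near-collinear",
            stacklevel=3,
        )


def assemble_extended_design(
    X: np.ndarray, Q: NoiseRegressorMatrix | np.ndarray, cond_limit: float = 1e6
) -> np.ndarray:
    """Stack [X | Q] and warn (never abort) on an ill-conditioned design."""
    Qm = Q.Q if isinstance(Q, NoiseRegressorMatrix) else np.asarray(Q, dtype=float)
    labels = Q.labels if isinstance(Q, NoiseRegressorMatrix) else None
    if Qm.shape[0] != X.shape[0]:
        raise ValueError(f"X has {X.shape[0]} rows but Q has {Qm.shape[0]}")
    if Qm.shape[1] == 0:
        return X
    XQ = np.concatenate([X, Qm], axis=1)
    cond = np.linalg.cond(XQ)
    if cond > cond_limit:
        detail = ""
        # name the most collinear column pair to guide the warning reader
        norms = np.linalg.norm(XQ, axis=0)
        ok = norms > 0
        U = XQ[:, ok] / norms[ok]
        G = np.abs(U.T @ U) - np.eye(int(ok.sum()))
        i, j = np.unravel_index(np.argmax(G), G.shape)
        names = [f"X{k}" for k in range(X.shape[1])] + (
            labels if labels is not None else [f"Q{k}" for k in range(Qm.shape[1])]
        )
        names = [n for n, keep in zip(names, ok) if keep]
        detail = f"; most collinear columns: {names[i]} ~ {names[j]} (|corr|={G[i, j]:.4f})"
        warnings.warn(
            f"extended design condition number {cond:.3g} exceeds {cond_limit:.0e}{detail}",
            stacklevel=2,
        )
    return XQ
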