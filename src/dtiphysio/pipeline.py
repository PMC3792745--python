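"""Workflow orchestration: fit the model family to a dataset and evaluate.

One ADC computation is shared by every model (identical input guarantees
metric comparability); the design matrix is assembled and solved
independently per slice, because the physiological regressors are sampled
at the true slice times and therefore change from slice to slice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import ModelSpec, assemble_extended_design, build_Q
from .io import GradientScheme, PhysioRecording, ROIMask, SliceTiming, VolumeSeries
from .metrics import (
    ErrorMap,
    adjusted_rms,
    delta_fa_percent,
    delta_rms_percent,
    ncfa,
    rician_mode,
)
from .models import RobustTensorLLS, TensorLLS
from .physio import phase_at_slices, sample_at_slices
from .tensor import build_tensor_design, compute_adc, fa, tensor_eigensystem

__all__ = ["ModelFit", "fit_models", "evaluate"]

DEFAULT_MODELS = (
    "standard",
    "lin_cardiac",
    "lin_cardiac_resp",
    "nonlin_cardiac",
    "nonlin_cardiac_lin_resp",
    "robust",
)


@dataclass
class ModelFit:
    """Per-voxel results of one model on one dataset."""

    spec: ModelSpec
    tensor: np.ndarray  # (x, y, z, 6)
    fa_map: np.ndarray
    md_map: np.ndarray
    error_map: ErrorMap
    residual: np.ndarray  # (x, y, z, N)
    noise_weight_maps: dict = field(default_factory=dict)  # label -> (x, y, z)
    robust_weights: np.ndarray | None = None  # (x, y, z, N)
    n_effective: np.ndarray | None = None
    converged: bool | None = None
    condition_numbers: list = field(default_factory=list)  # per slice

    @property
    def model_id(self) -> str:
        return self.spec.model_id


def _nan(shape) -> np.ndarray:
    out = np.empty(shape)
    out.fill(np.nan)
    return out


def fit_models(
    series: VolumeSeries,
    scheme: GradientScheme,
    timing: SliceTiming,
    physio: PhysioRecording | None = None,
    beat_times: np.ndarray | None = None,
    models=DEFAULT_MODELS,
    q0: float = 0.5,
    apod_width: float = 0.5,
    robust_max_iter: int = 20,
    robust_tol: float = 1e-4,
    brain_mask: np.ndarray | None = None,
    log=None,
) -> dict:
    """Fit the requested members of the model family; returns id -> ModelFit.

    Peripheral physiology is required only for the extended models with
    noise regressors; beat times may be supplied directly (e.g. from a
    trigger log or simulator ground truth), otherwise they are detected
    from the cardiac channel.
    """
    specs = [ModelSpec(m, q0=q0, apod_width=apod_width) for m in models]
    needs_physio = [s.model_id for s in specs if s.needs_physio]
    if needs_physio and physio is None:
        raise ValueError(
            f"peripheral physiology is required for model(s) {needs_physio} "
            "but no recording was provided"
        )

    adc = compute_adc(series, scheme)
    X = build_tensor_design(scheme)
    n_dir = X.shape[0]
    nx, ny, nz = series.shape

    regs = None
    if needs_physio:
        phases = phase_at_slices(physio, timing, peak_times=beat_times)
        regs = sample_at_slices(phases, timing)

    voxel_ok = adc.valid.all(axis=-1)
    if brain_mask is not None:
        voxel_ok = voxel_ok & brain_mask

    fits: dict = {}
    for spec in specs:
        tensor = _nan((nx, ny, nz, 6))
        residual = _nan((nx, ny, nz, n_dir))
        rms = _nan((nx, ny, nz))
        n_used = np.full((nx, ny, nz), float(n_dir))
        weight_maps = {}
        rweights = _nan((nx, ny, nz, n_dir)) if spec.is_robust else None
        n_eff = _nan((nx, ny, nz)) if spec.is_robust else None
        conds: list = []
        converged = True

        for z in range(nz):
            ok = voxel_ok[:, :, z]
            if not ok.any():
                conds.append(np.nan)
                continue
            y = adc.adc[:, :, z, :][ok].T  # (N, V)
            if spec.is_robust:
                est = RobustTensorLLS(max_iter=robust_max_iter, tol=robust_tol).fit(X, y)
                converged = converged and est.converged_
                rweights[:, :, z, :][ok] = est.weights_.T
                n_eff[:, :, z][ok] = est.n_effective_
                rms_z = adjusted_rms(
                    est.residual_, est.n_effective_, spec.p_total, inlier=est.inlier_
                )
                n_used[:, :, z][ok] = est.n_effective_
                conds.append(float(np.linalg.cond(X)))
            else:
                if spec.m > 0:
                    Qz = build_Q(spec, regs, scheme, z)
                    XQ = assemble_extended_design(X, Qz)
                else:
                    XQ = X
                est = TensorLLS().fit(XQ, y)
                rms_z = adjusted_rms(est.residual_, n_dir, spec.p_total)
                conds.append(float(np.linalg.cond(XQ)))
                if spec.m > 0:
                    for k, label in enumerate(Qz.labels):
                        weight_maps.setdefault(label, _nan((nx, ny, nz)))
                        weight_maps[label][:, :, z][ok] = est.noise_weights_[k]
            tensor[:, :, z, :][ok] = est.tensor_.T
            residual[:, :, z, :][ok] = est.residual_.T
            rms[:, :, z][ok] = rms_z

        if log is not None:
            log(f"model {spec.roman} {spec.model_id}: per-slice condition numbers "
                f"{np.round(conds, 1).tolist()}")

        evals, _ = tensor_eigensystem(tensor)
        fits[spec.model_id] = ModelFit(
            spec=spec,
            tensor=tensor,
            fa_map=fa(evals[..., 0], evals[..., 1], evals[..., 2]),
            md_map=evals.mean(axis=-1),
            error_map=ErrorMap(rms_adj=rms, n_used=n_used, p_used=spec.p_total),
            residual=residual,
            noise_weight_maps=weight_maps,
            robust_weights=rweights,
            n_effective=n_eff,
            converged=converged if spec.is_robust else None,
            condition_numbers=conds,
        )
    return fits


def evaluate(
    fits: dict,
    roi: ROIMask | np.ndarray | None = None,
    brain_mask: np.ndarray | None = None,
    reference: str = "robust",
    rician: bool = True,
) -> pd.DataFrame:
    """Per-model evaluation report against the standard tensor model.

    Columns: delta-rms percent over the whole brain and the ROI, relative
    FA change (percent) over the ROI, normalized cross-correlation of the
    FA-difference map against the reference (robust-fitting) model, and the
    mode of a Rician fit to the whole-brain adjusted-rms values.
    """
    if "standard" not in fits:
        raise ValueError("evaluation requires the standard-model fit")
    std = fits["standard"]
    ref_dfa = None
    if reference in fits and reference != "standard":
        ref_dfa = fits[reference].fa_map - std.fa_map

    rows = []
    for model_id, fit in fits.items():
        row = {"model": model_id, "label": fit.spec.roman, "p_total": fit.spec.p_total}
        if rician:
            vals = fit.error_map.rms_adj
            if brain_mask is not None:
                vals = vals[brain_mask]
            row["rician_mode"] = rician_mode(vals[np.isfinite(vals)]).mode
        if model_id != "standard":
            row["delta_rms_brain_pct"] = delta_rms_percent(
                fit.error_map, std.error_map, brain_mask
            )
            row["delta_rms_roi_pct"] = delta_rms_percent(fit.error_map, std.error_map, roi)
            row["delta_fa_pct"] = delta_fa_percent(fit.fa_map, std.fa_map, roi)
            if ref_dfa is not None and model_id != reference:
                row["ncfa_vs_ref"] = ncfa(fit.fa_map - std.fa_map, ref_dfa, roi)
        rows.append(row)
    return pd.DataFrame(rows).set_index("model")
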