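"""Assessment statistics for the model family.

* degrees-of-freedom-adjusted rms tensor-fit error,
  ``rms_adj = sqrt(sum eps_i^2 / (N - p))`` (for robust fits N is the
  effective number of inlier directions and only inlier residuals enter);
* difference maps of adjusted rms between a correction model and the
  standard model, and their ROI-level percent change (delta-rms);
* ROI-level relative FA change (delta-FA) between corrected and standard
  FA maps;
* zero-lag normalized cross-correlation (ncFA) between FA-difference maps,
  conventionally computed against the robust-fitting model as reference;
* a maximum-likelihood Rician fit to the rms-error values with mode
  extraction, summarizing the whole-brain error histogram.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

from .io import ROIMask

__all__ = [
    "ErrorMap",
    "RicianSummary",
    "adjusted_rms",
    "delta_rms_map",
    "delta_rms_percent",
    "delta_fa_percent",
    "ncfa",
    "rician_mode",
]


@dataclass
class ErrorMap:
    """Per-voxel adjusted rms tensor-fit error with its dof bookkeeping."""

    rms_adj: np.ndarray
    n_used: np.ndarray  # per-voxel effective number of directions
    p_used: int  # total regressor count p^(m) of the model


def adjusted_rms(eps: np.ndarray, n_used, p_used: int, inlier: np.ndarray | None = None):
    """sqrt( sum_i eps_i^2 / (n_used - p_used) ), NaN where n_used <= p_used.

    ``eps`` holds residuals with directions on axis 0.  For robust fits pass
    the per-voxel effective direction count as ``n_used`` and the inlier
    mask as ``inlier`` so only non-outlier residuals enter the sum.
    """
    eps = np.asarray(eps, dtype=float)
    sq = np.square(eps)
    if inlier is not None:
        sq = np.where(inlier, sq, 0.0)
    rss = np.sum(sq, axis=0)
    n_used = np.asarray(n_used, dtype=float)
    dof = n_used - p_used
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.sqrt(rss / dof)
    return np.where(dof > 0, out, np.nan)


def delta_rms_map(model_map: ErrorMap, standard_map: ErrorMap) -> np.ndarray:
    """Per-voxel rms_adj^(m) - rms_adj^(i).

    May be positive: correction can increase the adjusted error through the
    loss of degrees of freedom.
    """
    if model_map.rms_adj.shape != standard_map.rms_adj.shape:
        raise ValueError(
            f"grid mismatch: {model_map.rms_adj.shape} vs {standard_map.rms_adj.shape}"
        )
    return model_map.rms_adj - standard_map.rms_adj


def _roi_mean(values: np.ndarray, roi: ROIMask | np.ndarray | None) -> float:
    mask = roi.mask if isinstance(roi, ROIMask) else roi
    sel = values if mask is None else values[mask]
    return float(np.nanmean(sel))


def delta_rms_percent(model_map: ErrorMap, standard_map: ErrorMap, roi=None) -> float:
    """ROI-level percent change of adjusted rms relative to the standard model.

    Negative values mean the correction model explained noise; figures
    conventionally plot the negated value as a positive "reduction".
    """
    delta = delta_rms_map(model_map, standard_map)  # also checks the grids
    ref = _roi_mean(standard_map.rms_adj, roi)
    if not np.isfinite(ref) or ref == 0:
        raise ValueError("standard-model ROI mean rms is zero or undefined")
    return 100.0 * _roi_mean(delta, roi) / ref


def delta_fa_percent(fa_m: np.ndarray, fa_std: np.ndarray, roi=None) -> float:
    """100 * mean_ROI(|FA^(m) - FA^(i)|) / mean_ROI(FA^(i))."""
    fa_m = np.asarray(fa_m, dtype=float)
    fa_std = np.asarray(fa_std, dtype=float)
    if fa_m.shape != fa_std.shape:
        raise ValueError(f"grid mismatch: {fa_m.shape} vs {fa_std.shape}")
    ref = _roi_mean(fa_std, roi)
    if not np.isfinite(ref) or ref <= 0:
        raise ValueError("standard-model ROI mean FA is zero or undefined")
    return 100.0 * _roi_mean(np.abs(fa_m - fa_std), roi) / ref


def ncfa(delta_fa_m: np.ndarray, delta_fa_ref: np.ndarray, roi=None) -> float:
    """Zero-lag normalized cross-correlation of two FA-difference fields.

    sum(x*y) / sqrt(sum x^2 * sum y^2) over the ROI, without mean removal
    (this is a normalized cross-correlation, not a Pearson coefficient;
    see :func:`pearson_fa` for the centered variant).
    """
    mask = roi.mask if isinstance(roi, ROIMask) else roi
    x = np.asarray(delta_fa_m, dtype=float)
    y = np.asarray(delta_fa_ref, dtype=float)
    if mask is not None:
        x, y = x[mask], y[mask]
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 2:
        raise ValueError("need at least 2 ROI voxels")
    sx, sy = np.sum(x * x), np.sum(y * y)
    if sx == 0 or sy == 0:
        warnings.warn("zero-variance input to ncfa; returning NaN", stacklevel=2)
        return float("nan")
    return float(np.sum(x * y) / np.sqrt(sx * sy))


def pearson_fa(delta_fa_m, delta_fa_ref, roi=None) -> float:
    """Mean-centered (Pearson) variant of :func:`ncfa`, for sensitivity checks."""
    mask = roi.mask if isinstance(roi, ROIMask) else roi
    x = np.asarray(delta_fa_m, dtype=float)
    y = np.asarray(delta_fa_ref, dtype=float)
    if mask is not None:
        x, y = x[mask], y[mask]
    keep = np.isfinite(x) & np.isfinite(y)
    return ncfa(x[keep] - np.mean(x[keep]), y[keep] - np.mean(y[keep]))


# ---------------------------------------------------------------------------
# Rician summary of the error histogram


@dataclass
class RicianSummary:
    """Location nu, scale sigma and density mode of a fitted Rician."""

    nu: float
    sigma: float
    mode: float
    n_used: int
    n_dropped: int


def _rician_nll(params: np.ndarray, x: np.ndarray) -> float:
    nu, log_sigma = params
    nu = abs(nu)
    s2 = np.exp(2.0 * log_sigma)
    z = x * nu / s2
    # log I0 computed via the exponentially scaled Bessel for stability
    ll = (
        np.log(x)
        - 2.0 * log_sigma
        - (x * x + nu * nu) / (2.0 * s2)
        + np.log(special.i0e(z))
        + z
    )
    return -float(np.sum(ll))


def rician_mode(values: np.ndarray) -> RicianSummary:
    """Maximum-likelihood Rician fit on raw samples, with density-mode search.

    Non-positive values are dropped (their count is recorded); at least 100
    positive samples are required.  The fit is bin-free; histograms are for
    display only.
    """
    x = np.asarray(values, dtype=float).ravel()
    x = x[np.isfinite(x)]
    n_total = x.size
    x = x[x > 0]
    n_dropped = n_total - x.size
    if x.size < 100:
        raise ValueError(f"need >= 100 positive values, got {x.size}")

    m2 = np.mean(x * x)
    nu0 = np.sqrt(max(m2 - 2.0 * np.var(x), 0.0))
    sigma0 = max(np.std(x), 1e-12 * np.mean(x))
    res = optimize.minimize(
        _rician_nll,
        x0=np.array([nu0, np.log(sigma0)]),
        args=(x,),
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 2000},
    )
    if not res.success:
        raise RuntimeError(f"Rician fit failed: {res.message}")
    nu, sigma = abs(res.x[0]), float(np.exp(res.x[1]))

    dist = stats.rice(b=nu / sigma, scale=sigma)
    upper = np.sqrt(nu * nu + sigma * sigma) + 5.0 * sigma
    opt = optimize.minimize_scalar(
        lambda t: -dist.pdf(t), bounds=(1e-12, upper), method="bounded",
        options={"xatol": 1e-12 * upper},
    )
    return RicianSummary(
        nu=float(nu), sigma=sigma, mode=float(opt.x), n_used=int(x.size), n_dropped=int(n_dropped)
    )
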