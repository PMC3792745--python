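"""Standard diffusion tensor model: ADC inversion, design matrix, FA/MD.

The diffusion-weighted signal along direction ``g_i`` is
``S_i = S0 * exp(-b_i * g_i^T D g_i)``.  With a two-shell acquisition the
per-direction apparent diffusion coefficient is inverted against the mean
low-b reference image, ``adc_i = ln(S_ref / S_i) / (b_i - b_low)``, and the
six unique tensor elements ``d = (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz)`` solve the
linear model ``adc = X d + eps`` with design rows
``(gx^2, gy^2, gz^2, 2 gx gy, 2 gx gz, 2 gy gz)``.

Note the two-shell difference inversion is exact only when the reference
shell is b = 0 (or direction-matched); for a b=100 reference the small
direction-dependent bias lies in the span of ``X`` and therefore cancels in
every residual-based model comparison (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import GradientScheme, VolumeSeries

__all__ = [
    "AdcSeries",
    "compute_adc",
    "build_tensor_design",
    "tensor_eigensystem",
    "fa",
    "mean_diffusivity",
]


@dataclass
class AdcSeries:
    """Per-voxel, per-direction ADC (mm^2/s) for the high-b volumes.

    ``adc`` has shape (x, y, z, N) with N the number of high-b volumes;
    ``valid`` flags voxels/directions with positive signal.  ``b_eff`` is the
    effective b used in the inversion (b_i minus the reference-shell b).
    """

    adc: np.ndarray
    valid: np.ndarray
    b_eff: np.ndarray
    high_indices: np.ndarray
    scheme: GradientScheme = field(repr=False)

    @property
    def n_directions(self) -> int:
        return self.adc.shape[-1]


def compute_adc(series: VolumeSeries, scheme: GradientScheme) -> AdcSeries:
    """Invert the DW signal to per-direction ADCs against the mean low-b image.

    Voxels where any signal (or the reference) is non-positive are flagged
    invalid rather than raising; their adc entries are set to zero.
    """
    if series.n_volumes != scheme.n_volumes:
        raise ValueError(
            f"series has {series.n_volumes} volumes but scheme has {scheme.n_volumes}"
        )
    high = scheme.high_indices()
    low = np.where(scheme.is_low)[0]
    s_ref = series.data[..., low].mean(axis=-1)
    s_high = series.data[..., high]
    b_eff = scheme.b[high] - scheme.b_low

    valid = (s_high > 0) & (s_ref > 0)[..., None]
    with np.errstate(divide="ignore", invalid="ignore"):
        adc = np.log(s_ref[..., None] / s_high) / b_eff
    adc = np.where(valid, adc, 0.0)
    return AdcSeries(adc=adc, valid=valid, b_eff=b_eff, high_indices=high, scheme=scheme)


def design_row(g: np.ndarray) -> np.ndarray:
    g = np.asarray(g, dtype=float)
    gx, gy, gz = g[..., 0], g[..., 1], g[..., 2]
    return np.stack(
        [gx * gx, gy * gy, gz * gz, 2 * gx * gy, 2 * gx * gz, 2 * gy * gz], axis=-1
    )


def build_tensor_design(scheme: GradientScheme, rank_tol: float = 1e-10) -> np.ndarray:
    """N x 6 tensor design matrix from the high-b gradient directions.

    Column order is (xx, yy, zz, xy, xz, yz).  Raises if fewer than six
    directions are available or the matrix is rank-deficient.
    """
    g = scheme.g[scheme.is_high]
    if g.shape[0] < 6:
        raise ValueError(f"need >= 6 diffusion directions, got {g.shape[0]}")
    X = design_row(g)
    rank = np.linalg.matrix_rank(X, tol=rank_tol * np.linalg.norm(X))
    if rank < 6:
        raise ValueError(f"tensor design matrix is rank-deficient (rank {rank} < 6)")
    return X


def tensor_from_vec(d: np.ndarray) -> np.ndarray:
    """Assemble (..., 6) tensor vectors into symmetric (..., 3, 3) matrices."""
    d = np.asarray(d, dtype=float)
    T = np.empty(d.shape[:-1] + (3, 3))
    T[..., 0, 0] = d[..., 0]
    T[..., 1, 1] = d[..., 1]
    T[..., 2, 2] = d[..., 2]
    T[..., 0, 1] = T[..., 1, 0] = d[..., 3]
    T[..., 0, 2] = T[..., 2, 0] = d[..., 4]
    T[..., 1, 2] = T[..., 2, 1] = d[..., 5]
    return T


def tensor_eigensystem(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sorted (descending) eigenvalues and matching eigenvectors of d.

    ``d`` is a (..., 6) tensor vector; returns ``(evals, evecs)`` with
    ``evals[..., 0] >= evals[..., 1] >= evals[..., 2]`` and ``evecs[..., :, k]``
    the eigenvector of ``evals[..., k]``.
    """
    w, v = np.linalg.eigh(tensor_from_vec(d))
    order = np.argsort(w, axis=-1)[..., ::-1]
    evals = np.take_along_axis(w, order, axis=-1)
    evecs = np.take_along_axis(v, order[..., None, :], axis=-1)
    return evals, evecs


def fa(l1, l2, l3) -> np.ndarray:
    """Fractional anisotropy of the eigenvalue triple, in [0, 1].

    FA = sqrt(3/2) * ||lambda - mean|| / ||lambda||; defined as 0 where all
    eigenvalues vanish.  Negative eigenvalues are used as-is (no clipping),
    preserving the comparability of difference maps; callers may count
    voxels with l3 < 0 separately.
    """
    lam = np.stack(np.broadcast_arrays(l1, l2, l3), axis=-1).astype(float)
    mean = lam.mean(axis=-1, keepdims=True)
    num = np.sum((lam - mean) ** 2, axis=-1)
    den = np.sum(lam**2, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.sqrt(1.5 * num / den)
    return np.where(den > 0, out, 0.0)


def mean_diffusivity(l1, l2, l3) -> np.ndarray:
    return (np.asarray(l1) + np.asarray(l2) + np.asarray(l3)) / 3.0


def fa_from_vec(d: np.ndarray) -> np.ndarray:
    evals, _ = tensor_eigensystem(d)
    return fa(evals[..., 0], evals[..., 1], evals[..., 2])


def negative_eigenvalue_count(d: np.ndarray) -> int:
    evals, _ = tensor_eigensystem(d)
    return int(np.sum(evals[..., 2] < 0))
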