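"""Per-voxel tensor estimators (scikit-learn style).

``TensorLLS`` solves the (possibly extended) linear tensor model by
ordinary least squares for one design matrix and any number of voxels at
once; ``RobustTensorLLS`` adds iteratively reweighted least squares with a
Geman-McClure-type kernel whose spread is proportional to the median
absolute residual, down-weighting outlier directions (cardiac-locked
signal dropout, motion spikes) instead of modeling them.

Both estimators follow the scikit-learn contract: parameters in
``__init__``, all learned state in trailing-underscore attributes set by
``fit(X, y)``, ``get_params``/``set_params`` inherited from
``BaseEstimator``.  ``X`` is the (n_directions, n_regressors) design of one
slice and ``y`` the matching ADC samples, shaped (n_directions,) or
(n_directions, n_voxels).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "TensorLLS",
    "RobustTensorLLS",
    "effective_n",
    "fit_standard",
    "fit_extended",
    "fit_robust",
]

#: spread constant: C = C_FACTOR * median(|eps|).  3 x 1.4826 places the
#: outlier cut at three (MAD-estimated) standard deviations; see
#: docs/methods.md for why the cut sits in the tail rather than at one SD.
C_FACTOR = 3.0 * 1.4826


def _as_2d(y: np.ndarray) -> tuple[np.ndarray, bool]:
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        return y[:, None], True
    return y, False


class TensorLLS(RegressorMixin, BaseEstimator):
    """Ordinary least-squares fit of the (extended) tensor design.

    Parameters
    ----------
    rank_tol : float
        Relative tolerance of the design rank check.

    Attributes
    ----------
    coef_ : ndarray, (n_regressors, n_voxels) or (n_regressors,)
        All fitted regression weights.
    tensor_ : ndarray
        First six rows of ``coef_`` — the tensor vector
        (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz), mm^2/s.
    noise_weights_ : ndarray
        Remaining rows — the physiological-regressor weights ``p``.
    residual_ : ndarray, same shape as ``y``
        Tensor-fit error eps = y - X @ coef_.
    rss_ : ndarray
        Per-voxel sum of squared residuals.
    n_directions_, n_params_ : int
    """

    def __init__(self, rank_tol: float = 1e-10):
        self.rank_tol = rank_tol

    def _validate(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2D (n_directions, n_regressors)")
        n, p = X.shape
        if n <= p:
            raise ValueError(f"underdetermined fit: {n} directions for {p} regressors")
        if not np.all(np.isfinite(X)):
            raise ValueError("design matrix contains non-finite values")
        y2, squeeze = _as_2d(y)
        if y2.shape[0] != n:
            raise ValueError(f"y has {y2.shape[0]} rows, design has {n}")
        # identically-zero columns (e.g. a fully gated-out apodized regressor
        # block) carry no information: the model degenerates gracefully to
        # fewer effective regressors instead of a singular solve
        nonzero = np.any(X != 0.0, axis=0)
        Xa = X[:, nonzero]
        s = np.linalg.svd(Xa, compute_uv=False)
        if s[-1] <= self.rank_tol * s[0] * max(Xa.shape):
            rank = int(np.sum(s > self.rank_tol * s[0] * max(Xa.shape)))
            raise ValueError(f"singular design matrix (rank {rank} < {Xa.shape[1]})")
        return X, nonzero, y2, squeeze

    def fit(self, X, y):
        X, nonzero, y2, squeeze = self._validate(X, y)
        coef = np.zeros((X.shape[1], y2.shape[1]))
        coef[nonzero], _, _, _ = np.linalg.lstsq(X[:, nonzero], y2, rcond=None)
        self._finalize(X, y2, coef, squeeze)
        return self

    def _finalize(self, X, y2, coef, squeeze):
        resid = y2 - X @ coef
        if squeeze:
            coef, resid = coef[:, 0], resid[:, 0]
        self.coef_ = coef
        self.tensor_ = coef[:6]
        self.noise_weights_ = coef[6:]
        self.residual_ = resid
        self.rss_ = np.sum(np.square(resid), axis=0)
        self.n_directions_, self.n_params_ = X.shape

    def predict(self, X):
        return np.asarray(X, dtype=float) @ self.coef_


class RobustTensorLLS(TensorLLS):
    """IRLS tensor fit with median-proportional outlier down-weighting.

    Starting from the OLS solution, each iteration computes the residuals
    eps, the non-outlier spread ``C = c_factor * median(|eps|)`` per voxel,
    weights ``w = 1 / (1 + (eps/C)^2)^2``, and refits by weighted least
    squares; it stops when no weight moves by more than ``tol``.

    Extra attributes: ``weights_`` (per direction/voxel, in (0, 1]),
    ``C_`` (per voxel), ``inlier_`` (|eps| < C), ``n_effective_`` (inlier
    count per voxel), ``converged_``, ``n_iter_``.
    """

    def __init__(
        self,
        max_iter: int = 20,
        tol: float = 1e-4,
        c_factor: float = C_FACTOR,
        rank_tol: float = 1e-10,
    ):
        super().__init__(rank_tol=rank_tol)
        self.max_iter = max_iter
        self.tol = tol
        self.c_factor = c_factor

    def fit(self, X, y):
        X, _, y2, squeeze = self._validate(X, y)
        n, p = X.shape
        if n < 10:
            raise ValueError(f"robust fit needs >= 10 directions for headroom, got {n}")
        coef, _, _, _ = np.linalg.lstsq(X, y2, rcond=None)
        w = np.ones_like(y2)
        converged = False
        n_iter = 0
        # residuals at machine precision mean "no outliers", not a tiny spread
        c_floor = 1e-10 * np.maximum(np.max(np.abs(y2), axis=0), 1e-300)
        for n_iter in range(1, self.max_iter + 1):
            eps = y2 - X @ coef
            C = self.c_factor * np.median(np.abs(eps), axis=0)
            degenerate = C <= c_floor  # (near-)zero residuals: keep w = 1
            Cs = np.where(degenerate, 1.0, C)
            w_new = 1.0 / np.square(1.0 + np.square(eps / Cs))
            w_new[:, degenerate] = 1.0
            delta = np.max(np.abs(w_new - w))
            w = w_new
            # batched weighted normal equations (p is small)
            A = np.einsum("np,nv,nq->vpq", X, w, X, optimize=True)
            rhs = np.einsum("np,nv,nv->vp", X, w, y2, optimize=True)
            coef = np.linalg.solve(A, rhs[:, :, None])[:, :, 0].T
            if delta < self.tol:
                converged = True
                break
        eps = y2 - X @ coef
        C = self.c_factor * np.median(np.abs(eps), axis=0)
        inlier = np.abs(eps) < np.where(C <= c_floor, np.inf, C)
        self._finalize(X, y2, coef, squeeze)
        if squeeze:
            w, inlier, C = w[:, 0], inlier[:, 0], C[0] if C.ndim else C
        self.weights_ = w
        self.C_ = C
        self.inlier_ = inlier
        self.n_effective_ = np.sum(inlier, axis=0)
        self.converged_ = converged
        self.n_iter_ = n_iter
        return self


def effective_n(eps: np.ndarray, C) -> np.ndarray:
    """Number of directions whose |residual| falls inside the spread C."""
    C = np.asarray(C, dtype=float)
    if np.any(C <= 0):
        raise ValueError("spread C must be positive")
    return np.sum(np.abs(np.asarray(eps)) < C, axis=0)


# ---------------------------------------------------------------------------
# thin functional wrappers


def fit_standard(adc: np.ndarray, X: np.ndarray) -> TensorLLS:
    """Standard tensor model: OLS of adc on the 6-column design."""
    return TensorLLS().fit(X, adc)


def fit_extended(adc: np.ndarray, X: np.ndarray, Q) -> TensorLLS:
    """Extended tensor model: OLS of adc on [X | Q].

    With an empty Q this is, by construction, the very same computation as
    :func:`fit_standard` (the extended model reduces to the standard one).
    """
    from .design import assemble_extended_design

    return TensorLLS().fit(assemble_extended_design(X, Q), adc)


def fit_robust(adc: np.ndarray, X: np.ndarray, max_iter: int = 20, tol: float = 1e-4) -> RobustTensorLLS:
    """Robust (outlier down-weighting) tensor fit on the 6-column design."""
    return RobustTensorLLS(max_iter=max_iter, tol=tol).fit(X, adc)
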