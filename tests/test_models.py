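import numpy as np
import pytest

from dtiphysio.design import assemble_extended_design
from dtiphysio.models import (
    RobustTensorLLS,
    TensorLLS,
    effective_n,
    fit_extended,
    fit_robust,
    fit_standard,
)
from dtiphysio.tensor import build_tensor_design

D_TRUE = np.array([1.7e-3, 0.2e-3, 0.2e-3, 0.1e-3, 0.0, 0.05e-3])


@pytest.fixture(scope="module")
def X(scheme60_module):
    return build_tensor_design(scheme60_module)


@pytest.fixture(scope="module")
def scheme60_module():
    from dtiphysio import make_scheme

    return make_scheme(seed=0)


class TestExtendedFit:
    def test_zero_regressor_extension_is_bit_identical_to_standard(self, X, rng):
        y = (X @ D_TRUE)[:, None] + 1e-5 * rng.normal(size=(X.shape[0], 7))
        std = fit_standard(y, X)
        ext = fit_extended(y, X, np.empty((X.shape[0], 0)))
        np.testing.assert_array_equal(std.coef_, ext.tensor_)
        np.testing.assert_array_equal(std.residual_, ext.residual_)

    def test_all_zero_q_columns_degrade_to_standard(self, X, rng):
        """A fully gated-out regressor block must not destabilize the fit."""
        y = X @ D_TRUE + 1e-5 * rng.normal(size=X.shape[0])
        std = fit_standard(y, X)
        ext = fit_extended(y, X, np.zeros((X.shape[0], 2)))
        np.testing.assert_array_equal(ext.tensor_, std.tensor_)
        np.testing.assert_array_equal(ext.noise_weights_, 0.0)

    def test_nesting_rss_never_increases(self, X, rng):
        y = X @ D_TRUE + 1e-4 * rng.normal(size=X.shape[0])
        Q = rng.normal(size=(X.shape[0], 4))
        std = fit_standard(y, X)
        ext = fit_extended(y, X, Q)
        assert ext.rss_ <= std.rss_ + 1e-25

    def test_recovery_of_in_span_perturbation(self, X, rng):
        Q = rng.normal(size=(X.shape[0], 4)) / 600.0
        p_true = np.array([3e-2, -1e-2, 5e-3, 0.0])
        y = X @ D_TRUE + Q @ p_true
        ext = fit_extended(y, X, Q)
        np.testing.assert_allclose(ext.tensor_, D_TRUE, rtol=1e-10, atol=1e-15)
        np.testing.assert_allclose(ext.noise_weights_, p_true, rtol=1e-9, atol=1e-15)

    def test_noise_weights_vanish_on_clean_data(self, X, rng):
        Q = rng.normal(size=(X.shape[0], 4)) / 600.0
        ext = fit_extended(X @ D_TRUE, X, Q)
        np.testing.assert_allclose(ext.noise_weights_, 0.0, atol=1e-12)

    def test_underdetermined_fit_rejected(self, rng):
        X = rng.normal(size=(8, 6))
        Q = rng.normal(size=(8, 4))
        with pytest.raises(ValueError, match="underdetermined"):
            fit_extended(rng.normal(size=8), X, Q)

    def test_sklearn_param_interface(self):
        est = TensorLLS(rank_tol=1e-8)
        assert est.get_params()["rank_tol"] == 1e-8
        est.set_params(rank_tol=1e-9)
        assert est.rank_tol == 1e-9


class TestRobustFit:
    def test_consistent_data_keeps_all_weights_at_one(self, X):
        est = fit_robust(X @ D_TRUE, X)
        np.testing.assert_array_equal(est.weights_, 1.0)
        np.testing.assert_allclose(est.tensor_, D_TRUE, rtol=1e-10, atol=1e-15)
        assert est.converged_

    def test_dropout_direction_downweighted_and_fit_improved(self, X, rng):
        y = X @ D_TRUE + 2e-6 * rng.normal(size=X.shape[0])
        y_out = y.copy()
        y_out[13] += np.log(2.0) / 600.0  # 50% signal dropout on one direction
        ols = fit_standard(y_out, X)
        rob = fit_robust(y_out, X)
        assert rob.weights_[13] < 0.2
        err_ols = np.linalg.norm(ols.tensor_ - D_TRUE)
        err_rob = np.linalg.norm(rob.tensor_ - D_TRUE)
        assert err_rob < err_ols

    def test_permutation_equivariance(self, X, rng):
        y = X @ D_TRUE + 1e-5 * rng.normal(size=X.shape[0])
        y[5] += 1e-3
        perm = rng.permutation(X.shape[0])
        a = fit_robust(y, X)
        b = fit_robust(y[perm], X[perm])
        np.testing.assert_allclose(a.tensor_, b.tensor_, rtol=1e-10)
        np.testing.assert_allclose(a.weights_[perm], b.weights_, rtol=1e-8)

    def test_scale_equivariance_of_weights(self, X, rng):
        y = X @ D_TRUE + 1e-5 * rng.normal(size=X.shape[0])
        y[7] += 5e-4
        a = fit_robust(y, X)
        b = fit_robust(10.0 * y, X)
        np.testing.assert_allclose(b.tensor_, 10.0 * a.tensor_, rtol=1e-9)
        np.testing.assert_allclose(b.weights_, a.weights_, rtol=1e-9)

    def test_no_outlier_gaussian_fit_close_to_ols(self, X, rng):
        """With purely Gaussian residuals the robust tensor typically stays
        within 0.5% of the OLS tensor at N=60 (the deviation scales with the
        noise level; 2e-5 mm^2/s here is ~1% of the tensor norm)."""
        y = (X @ D_TRUE)[:, None] + 2e-5 * rng.normal(size=(X.shape[0], 50))
        ols = fit_standard(y, X)
        rob = fit_robust(y, X)
        rel = np.linalg.norm(rob.tensor_ - ols.tensor_, axis=0) / np.linalg.norm(
            ols.tensor_, axis=0
        )
        assert np.median(rel) < 5e-3
        assert rel.max() < 2e-2

    def test_needs_headroom(self, rng):
        X = rng.normal(size=(8, 6))
        with pytest.raises(ValueError, match="headroom"):
            fit_robust(rng.normal(size=8), X)

    def test_reports_iterations_and_multivoxel_shapes(self, X, rng):
        y = (X @ D_TRUE)[:, None] + 1e-5 * rng.normal(size=(X.shape[0], 11))
        est = RobustTensorLLS().fit(X, y)
        assert est.weights_.shape == y.shape
        assert est.n_effective_.shape == (11,)
        assert 1 <= est.n_iter_ <= est.max_iter


class TestEffectiveN:
    def test_direct_count(self):
        eps = np.array([0.1, 0.2, 5.0])
        assert effective_n(eps, 1.0) == 2

    def test_all_zero_residuals_count_everything(self):
        assert effective_n(np.zeros(60), 1.0) == 60

    def test_gaussian_fraction_inside_mad_sigma(self, rng):
        """Monte-Carlo oracle: with C = 1.4826*median|eps| (a MAD sigma
        estimate), the inlier fraction of Gaussian residuals is
        P(|Z| < 1) = 0.683."""
        eps = rng.normal(size=(60, 4000))
        C = 1.4826 * np.median(np.abs(eps), axis=0)
        frac = effective_n(eps, C) / 60.0
        assert np.mean(frac) == pytest.approx(0.683, abs=0.01)

    def test_nonpositive_spread_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            effective_n(np.zeros(3), 0.0)
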