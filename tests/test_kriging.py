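"""Variogram estimation/fitting and ordinary/global kriging numerics."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from echoscape.kriging import (
    VariogramModel,
    cross_validate,
    empirical_variogram,
    fit_variogram,
    global_kriging,
    ordinary_kriging,
)


def dense_ok_oracle(pts, z, model, target):
    """Brute-force solve of the full ordinary-kriging system."""
    n = len(pts)
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = model(cdist(pts, pts))
    A[n, :n] = A[:n, n] = 1.0
    b = np.r_[model(cdist(pts, np.atleast_2d(target))).ravel(), 1.0]
    sol = np.linalg.solve(A, b)
    lam = sol[:n]
    return lam @ z, lam @ b[:n] + sol[n], lam


class TestVariogramModel:
    def test_zero_at_origin_and_nondecreasing(self):
        for fam in ("spherical", "exponential", "gaussian"):
            m = VariogramModel(fam, 0.3, 1.0, 50.0)
            h = np.linspace(0, 200, 400)
            g = m(h)
            assert g[0] == 0.0
            assert np.all(np.diff(g) >= -1e-12)
            assert g[-1] == pytest.approx(m.sill, rel=1e-3)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            VariogramModel("spherical", -0.1, 1.0, 10.0)
        with pytest.raises(ValueError):
            VariogramModel("cubic", 0.0, 1.0, 10.0)


class TestEmpiricalVariogram:
    def test_constant_field_is_zero(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 10, (50, 2))
        lags, gamma, _ = empirical_variogram(pts, np.full(50, 3.0))
        assert np.nanmax(gamma) == 0.0

    def test_three_point_hand_example(self):
        """Values 0,1,2 at unit spacing: gamma(1) = 0.5, gamma(2) = 2."""
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        z = np.array([0.0, 1.0, 2.0])
        lags, gamma, counts = empirical_variogram(pts, z, n_lags=5, max_lag=2.5)
        g1 = gamma[np.digitize(1.0, np.linspace(0, 2.5, 6)) - 1]
        g2 = gamma[np.digitize(2.0, np.linspace(0, 2.5, 6)) - 1]
        assert g1 == pytest.approx(0.5)
        assert g2 == pytest.approx(2.0)
        assert counts.sum() == 3

    def test_white_noise_flat_at_variance(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 100, (500, 2))
        z = rng.normal(0, 2.0, 500)
        _, gamma, counts = empirical_variogram(pts, z, n_lags=10)
        est = np.average(gamma[np.isfinite(gamma)], weights=counts[np.isfinite(gamma)])
        assert est == pytest.approx(4.0, rel=0.15)

    def test_identical_locations_raise(self):
        with pytest.raises(ValueError):
            empirical_variogram(np.zeros((5, 2)), np.arange(5.0))


class TestFitVariogram:
    def test_recovers_known_model(self):
        m = VariogramModel("exponential", 0.2, 1.0, 40.0)
        lags = np.linspace(2, 120, 20)
        fitted = fit_variogram(lags, m(lags), family="exponential")
        assert fitted.nugget == pytest.approx(0.2, abs=0.05)
        assert fitted.sill == pytest.approx(1.2, rel=0.05)
        assert fitted.range_ == pytest.approx(40.0, rel=0.15)

    def test_family_selection_prefers_truth(self):
        m = VariogramModel("gaussian", 0.0, 2.0, 60.0)
        lags = np.linspace(2, 150, 25)
        fitted = fit_variogram(lags, m(lags))
        assert np.allclose(fitted(lags), m(lags), atol=0.02)


class TestOrdinaryKriging:
    def test_constant_data_reproduced_everywhere(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 100, (30, 2))
        m = VariogramModel("spherical", 0.0, 1.0, 50.0)
        tgt = rng.uniform(0, 100, (40, 2))
        est, _ = ordinary_kriging(pts, np.full(30, 5.0), m, tgt)
        assert np.allclose(est, 5.0)

    def test_exact_interpolation_with_zero_nugget(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 100, (25, 2))
        z = rng.normal(0, 1, 25)
        m = VariogramModel("exponential", 0.0, 1.0, 60.0)
        est, var = ordinary_kriging(pts, z, m, pts, n_neighbors=None)
        assert np.allclose(est, z, atol=1e-8)
        assert np.allclose(var, 0.0, atol=1e-8)

    def test_matches_dense_oracle_to_1e8(self):
        """Moving-neighbourhood solve == brute-force system on <=32 points."""
        rng = np.random.default_rng(4)
        for n in (5, 20, 32):
            pts = rng.uniform(0, 100, (n, 2))
            z = rng.normal(0, 1, n)
            m = VariogramModel("spherical", 0.1, 1.0, 70.0)
            tgt = rng.uniform(0, 100, (7, 2))
            est, var = ordinary_kriging(pts, z, m, tgt, n_neighbors=32)
            for j, t in enumerate(tgt):
                e0, v0, lam = dense_ok_oracle(pts, z, m, t)
                assert est[j] == pytest.approx(e0, abs=1e-8 * max(1, abs(e0)))
                assert var[j] == pytest.approx(v0, abs=1e-8 * max(1, abs(v0)))
                assert lam.sum() == pytest.approx(1.0, abs=1e-10)

    def test_duplicate_points_handled_by_drop(self):
        pts = np.array([[0.0, 0.0], [0.0, 0.0], [10.0, 0.0]])
        z = np.array([1.0, 1.0, 2.0])
        m = VariogramModel("spherical", 0.0, 1.0, 20.0)
        with pytest.warns(UserWarning, match="duplicate"):
            est, _ = ordinary_kriging(pts, z, m, np.array([[5.0, 0.0]]))
        assert 1.0 <= est[0] <= 2.0

    def test_cross_validation_standardised_error_calibrated(self):
        """With the true variogram, LOO mean standardised squared error ~ 1."""
        rng = np.random.default_rng(5)
        n = 150
        pts = rng.uniform(0, 1000, (n, 2))
        m = VariogramModel("exponential", 0.05, 1.0, 300.0)
        C = m.sill - m(cdist(pts, pts))
        np.fill_diagonal(C, m.sill)
        z = np.linalg.cholesky(C + 1e-9 * np.eye(n)) @ rng.standard_normal(n)
        pred, kv = cross_validate(pts, z, m)
        msse = np.mean((pred - z) ** 2 / kv)
        assert 0.7 <= msse <= 1.3


class TestGlobalKriging:
    def test_single_datum_pure_nugget_closed_form(self):
        m = VariogramModel("spherical", 0.5, 1e-9, 1.0)
        rng = np.random.default_rng(6)
        domain = rng.uniform(0, 1000, (800, 2))  # h=0 pairs have measure ~0
        mean, var = global_kriging(np.array([[500.0, 500.0]]), np.array([3.0]), m, domain)
        assert mean == pytest.approx(3.0)
        assert var == pytest.approx(0.5, rel=0.01)

    def test_matches_dense_polygon_oracle(self):
        """5-datum global mean/variance vs direct evaluation, 10^3 grid points."""
        rng = np.random.default_rng(7)
        pts = rng.uniform(0, 100, (5, 2))
        z = rng.normal(0, 1, 5)
        m = VariogramModel("exponential", 0.1, 1.0, 50.0)
        gx, gy = np.meshgrid(np.linspace(2, 98, 32), np.linspace(2, 98, 32))
        domain = np.c_[gx.ravel(), gy.ravel()]
        # oracle: bordered system with point-to-domain mean semivariances
        A = np.zeros((6, 6))
        A[:5, :5] = m(cdist(pts, pts))
        A[5, :5] = A[:5, 5] = 1.0
        b = np.r_[m(cdist(pts, domain)).mean(axis=1), 1.0]
        sol = np.linalg.solve(A, b)
        gvv = m(cdist(domain, domain)).mean()
        mean0 = sol[:5] @ z
        var0 = sol[:5] @ b[:5] + sol[5] - gvv
        mean, var = global_kriging(pts, z, m, domain)
        assert mean == pytest.approx(mean0, abs=1e-6)
        assert var == pytest.approx(var0, abs=1e-6)
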