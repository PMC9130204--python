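"""Indicator coding, MAF decorrelation, recombination and Eq.-style conversion."""

import numpy as np
import pytest
from shapely.geometry import Polygon

from echoscape.biomass import (
    AcousticBiomassModel,
    compute_maf,
    estimate_biomass,
    global_krige_maf,
    indicator_code,
    recombine,
)
from echoscape.kriging import VariogramModel


def zero_inflated_sample(rng, n, presence=0.4, mu=5.0, sigma=1.0):
    return np.where(rng.random(n) < presence, np.exp(rng.normal(mu, sigma, n)), 0.0)


class TestIndicatorCoding:
    def test_zero_maps_to_null_class(self):
        v = np.concatenate([[0.0], np.arange(1.0, 41.0)])
        cod = indicator_code(v)
        assert np.array_equal(cod.indicators[0], [1, 0, 0, 0, 0])

    def test_indicators_sum_to_one_always(self):
        rng = np.random.default_rng(0)
        cod = indicator_code(zero_inflated_sample(rng, 500))
        assert np.array_equal(cod.indicators.sum(axis=1), np.ones(500))

    def test_quantile_classes_of_1_to_100(self):
        """With positives 1..100, 96 exceeds the 95% cut -> top class."""
        v = np.concatenate([np.zeros(30), np.arange(1.0, 101.0)])
        cod = indicator_code(v)
        cls = cod.indicators.argmax(axis=1)
        assert cls[np.where(v == 96.0)[0][0]] == 4
        assert cls[np.where(v == 10.0)[0][0]] == 1
        assert cls[np.where(v == 50.0)[0][0]] == 2
        assert cls[np.where(v == 80.0)[0][0]] == 3

    def test_tie_at_cut_goes_to_lower_class(self):
        v = np.concatenate([np.zeros(5), np.repeat([1.0, 2.0, 3.0, 4.0], 25)])
        cod = indicator_code(v)
        cls = cod.indicators.argmax(axis=1)
        cuts = cod.cuts
        at_cut = np.isclose(v, cuts[0])
        assert np.all(cls[at_cut] == 1)

    def test_all_zero_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            indicator_code(np.zeros(50))

    def test_class_means_weighted_sum_is_sample_mean(self):
        rng = np.random.default_rng(1)
        v = zero_inflated_sample(rng, 400)
        cod = indicator_code(v)
        p = cod.class_counts / len(v)
        assert p @ cod.class_means == pytest.approx(v.mean())


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(2)
    n = 600
    xy = rng.uniform(0, 1000, (n, 2))
    cod = indicator_code(zero_inflated_sample(rng, n))
    maf = compute_maf(cod.indicators, xy)
    return cod, maf, xy


class TestMAF:

    def test_lag0_exact_decorrelation(self, fitted):
        cod, maf, _ = fitted
        F = maf.factors(cod.indicators)
        corr = np.corrcoef(F.T)
        off = np.abs(corr - np.eye(len(corr))).max()
        assert off < 1e-8

    def test_unit_variance_factors(self, fitted):
        cod, maf, _ = fitted
        F = maf.factors(cod.indicators)
        assert np.allclose(F.var(axis=0), 1.0, atol=1e-8)

    def test_rank_is_classes_minus_one(self, fitted):
        _, maf, _ = fitted
        assert maf.n_factors == 4

    def test_eigenvalues_ordered_most_continuous_first(self, fitted):
        _, maf, _ = fitted
        assert np.all(np.diff(maf.eigenvalues) >= 0)

    def test_short_lag_decorrelation_on_white_noise(self):
        """Independent white-noise indicators stay uncorrelated at lag h."""
        rng = np.random.default_rng(3)
        n = 800
        xy = rng.uniform(0, 1000, (n, 2))
        Z = (rng.random((n, 2)) < 0.5).astype(float)
        maf = compute_maf(Z, xy)
        F = maf.factors(Z)
        from echoscape.biomass import _lag_pairs

        pairs = _lag_pairs(xy, maf.h, maf.h_tol)
        d = F[pairs[:, 0]] - F[pairs[:, 1]]
        inc_corr = np.corrcoef(d.T)
        assert np.abs(inc_corr - np.eye(2)).max() < 0.1

    def test_single_indicator_is_standardised_self(self):
        rng = np.random.default_rng(4)
        n = 300
        xy = rng.uniform(0, 500, (n, 2))
        z = rng.normal(2.0, 3.0, (n, 1))
        maf = compute_maf(z, xy)
        F = maf.factors(z)
        zstd = (z[:, 0] - z[:, 0].mean()) / z[:, 0].std()
        assert np.allclose(np.abs(F[:, 0]), np.abs(zstd), atol=1e-8)

    def test_no_pairs_at_lag_errors_with_suggestion(self):
        xy = np.array([[0.0, 0.0], [1000.0, 0.0], [2000.0, 0.0]])
        Z = np.eye(3)
        with pytest.raises(ValueError, match="lag"):
            compute_maf(Z, xy, h=10.0, h_tol=1.0)


class TestRecombine:
    def test_identity_on_uncorrelated_indicators(self):
        rng = np.random.default_rng(5)
        n = 500
        xy = rng.uniform(0, 1000, (n, 2))
        v = zero_inflated_sample(rng, n)
        cod = indicator_code(v)
        maf = compute_maf(cod.indicators, xy)
        F = maf.factors(cod.indicators)
        # "global means" taken as the exact sample means of the factors
        mean_sa, var, p = recombine(F.mean(axis=0), np.zeros(maf.n_factors), maf, cod)
        assert p.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.allclose(p, cod.class_counts / n, atol=1e-8)
        assert mean_sa == pytest.approx(v.mean(), rel=1e-8)
        assert var == 0.0

    def test_constant_factor_gives_zero_variance(self):
        rng = np.random.default_rng(6)
        xy = rng.uniform(0, 100, (50, 2))
        F = np.ones((50, 1))
        means, variances, _ = global_krige_maf(F, xy, Polygon([(0, 0), (100, 0), (100, 100), (0, 100)]))
        assert means[0] == 1.0 and variances[0] == 0.0

    def test_single_datum_pure_nugget_factor(self):
        m = VariogramModel("spherical", 0.4, 1e-9, 1.0)
        means, variances, _ = global_krige_maf(
            np.array([[2.5]]), np.array([[50.0, 50.0]]),
            Polygon([(0, 0), (100, 0), (100, 100), (0, 100)]),
            variograms=[m],
        )
        assert means[0] == pytest.approx(2.5)
        assert variances[0] == pytest.approx(0.4, rel=0.05)


class TestBiomassConversion:
    def test_zero_mean_sa_gives_zero_tonnes(self):
        assert estimate_biomass(0.0, 1e6).biomass_t == 0.0

    def test_reference_arithmetic(self):
        """1000 m^2 nmi^-2 over 1 km^2 at W=485 g, TS=-39.3 dB ~ 95.8 t."""
        est = estimate_biomass(1000.0, 1e6, 485.0, -39.3)
        assert est.biomass_t == pytest.approx(95.7745, rel=1e-4)
        assert est.density_g_m2 == pytest.approx(95.7745, rel=1e-4)

    def test_default_species_constants(self):
        est = estimate_biomass(10.0, 1e6)
        assert est.weight_g == 485.0 and est.ts_db == -39.3

    def test_linear_in_drivers_and_ts_decade(self):
        base = estimate_biomass(100.0, 1e6, 485.0, -39.3).biomass_t
        assert estimate_biomass(200.0, 1e6, 485.0, -39.3).biomass_t == pytest.approx(2 * base)
        assert estimate_biomass(100.0, 2e6, 485.0, -39.3).biomass_t == pytest.approx(2 * base)
        assert estimate_biomass(100.0, 1e6, 970.0, -39.3).biomass_t == pytest.approx(2 * base)
        assert estimate_biomass(100.0, 1e6, 485.0, -29.3).biomass_t == pytest.approx(base / 10)

    def test_implausible_ts_warns(self):
        with pytest.warns(UserWarning, match="implausible"):
            estimate_biomass(10.0, 1e6, ts_db=5.0)

    def test_cv_is_sd_over_mean(self):
        est = estimate_biomass(100.0, 1e6, mean_sa_variance=400.0)
        assert est.cv == pytest.approx(0.2)


class TestModelInterface:
    def test_fit_and_summary(self):
        rng = np.random.default_rng(7)
        n = 400
        xy = rng.uniform(0, 2000, (n, 2))
        sa = zero_inflated_sample(rng, n)
        poly = Polygon([(0, 0), (2000, 0), (2000, 2000), (0, 2000)])
        res = AcousticBiomassModel(sa, xy, poly).fit(grid_points=300)
        assert res.biomass_t > 0
        assert 0 < res.cv < 1
        assert res.indicator_means.sum() == pytest.approx(1.0, abs=1e-6)
        lo, hi = res.conf_int()
        assert lo < res.biomass_t < hi or lo == 0.0
        text = res.summary()
        assert "biomass" in text and "CV" in text

    def test_from_esdu_selects_label_column(self):
        import pandas as pd

        rng = np.random.default_rng(8)
        n = 300
        df = pd.DataFrame(
            {
                "x": rng.uniform(0, 1000, n),
                "y": rng.uniform(0, 1000, n),
                "sa_fish": zero_inflated_sample(rng, n),
                "sa_M. niger": zero_inflated_sample(rng, n),
            }
        )
        poly = Polygon([(0, 0), (1000, 0), (1000, 1000), (0, 1000)])
        m = AcousticBiomassModel.from_esdu(df, poly, label="M. niger")
        assert len(m.sa) == n
        with pytest.raises(KeyError):
            AcousticBiomassModel.from_esdu(df, poly, label="sand fish")
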