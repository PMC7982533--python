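"""Persistency measures, variance propagation, heritability, trends."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rrlact.basis import LegendreBasis, pm1_contrast, pm2_contrast, pm3_contrast, standard_contrasts, total270_contrast
from rrlact.model import ModelSolution
from rrlact.persistency import (
    build_report,
    genetic_correlation,
    genetic_trend,
    genetic_variance,
    heritability,
    pe_variance,
    pm_value,
    residual_multiplier,
    residual_variance_of_measure,
)


def random_pd(k, seed):
    rng = np.random.default_rng(seed)
    B = rng.normal(size=(k, k))
    return B @ B.T + 0.1 * np.eye(k)


def solution_for(coeffs):
    return ModelSolution(fixed=pd.Series(dtype=float),
                         a_hat=pd.DataFrame([np.asarray(coeffs)], index=[1]),
                         pe_hat=pd.DataFrame(), diagnostics={})


class TestPMValue:
    def test_flat_curve_gives_zero_for_all_measures(self):
        basis = LegendreBasis(5)
        sol = solution_for([1 / np.sqrt(0.5), 0, 0, 0, 0])
        for m in ("PM1", "PM2", "PM3"):
            assert pm_value(sol, 1, m, basis) == pytest.approx(0.0, abs=1e-12)

    def test_pm3_order1_unit_matches_printed_element(self):
        basis = LegendreBasis(5)
        sol = solution_for([0.0, 1.0, 0.0, 0.0, 0.0])
        assert pm_value(sol, 1, "PM3", basis) == pytest.approx(1.6361, abs=2e-4)

    def test_contrast_equals_daily_ebv_arithmetic(self):
        rng = np.random.default_rng(4)
        basis = LegendreBasis(5)
        grid = basis.grid()
        for _ in range(50):
            coeffs = rng.normal(size=5)
            sol = solution_for(coeffs)
            ebv = grid @ coeffs
            day = dict(zip(range(5, 271), ebv))
            pm1 = np.mean([day[t] for t in range(226, 271)]) - np.mean([day[t] for t in range(44, 63)])
            pm2 = np.mean([day[t] - day[248] for t in range(53, 248)])
            pm3 = day[257] - day[80]
            assert pm_value(sol, 1, "PM1", basis) == pytest.approx(pm1, abs=1e-10)
            assert pm_value(sol, 1, "PM2", basis) == pytest.approx(pm2, abs=1e-10)
            assert pm_value(sol, 1, "PM3", basis) == pytest.approx(pm3, abs=1e-10)

    def test_unknown_measure_rejected(self):
        with pytest.raises(ValueError, match="unknown measure"):
            pm_value(solution_for([0, 0, 0]), 1, "PM9", LegendreBasis(3))


class TestQuadraticForms:
    def test_identity_covariance_gives_squared_norm(self):
        basis = LegendreBasis(3)
        c = pm3_contrast(basis)
        assert genetic_variance(c, np.eye(3)) == pytest.approx(float(c.weights @ c.weights))

    def test_zero_covariance_gives_zero(self):
        c = pm2_contrast(LegendreBasis(3))
        assert pe_variance(c, np.zeros((3, 3))) == 0.0

    def test_loop_oracle(self):
        basis = LegendreBasis(3)
        K = random_pd(3, 1)
        c = pm1_contrast(basis)
        loop = sum(c.weights[i] * K[i, j] * c.weights[j] for i in range(3) for j in range(3))
        assert genetic_variance(c, K) == pytest.approx(loop, rel=1e-12)

    def test_dimension_mismatch_is_error(self):
        with pytest.raises(ValueError):
            genetic_variance(pm3_contrast(LegendreBasis(5)), np.eye(3))


class TestResidualPropagation:
    def test_printed_multipliers(self):
        # PM3 doubles the daily residual; the 270-day sum scales it by 266
        assert residual_multiplier("PM3") == 2.0
        assert residual_multiplier("TOTAL270", "sum") == 266.0

    def test_pm1_multiplier_from_daily_weights(self):
        # sum of squared daily weights over the true window lengths 45 and 19
        w = np.r_[np.full(45, 1 / 45), np.full(19, -1 / 19)]
        assert residual_multiplier("PM1") == pytest.approx(float(w @ w), rel=1e-12)
        assert residual_multiplier("PM1") == pytest.approx(1 / 45 + 1 / 19, rel=1e-12)

    def test_pm2_multiplier_per_day_scale(self):
        w = np.r_[np.full(195, 1 / 195), -1.0]
        assert residual_multiplier("PM2") == pytest.approx(float(w @ w), rel=1e-12)

    def test_measure_residual_scales_with_sigma(self):
        assert residual_variance_of_measure("PM3", 0.03) == pytest.approx(0.06)
        with pytest.raises(ValueError):
            residual_variance_of_measure("PM3", -1.0)


class TestHeritability:
    def test_arithmetic(self):
        assert heritability(1.0, 1.0, 2.0) == 0.25
        assert heritability(0.0, 0.5, 0.7) == 0.0
        assert heritability(2.0, 0.0, 0.0) == 1.0

    def test_all_zero_denominator(self):
        with pytest.raises(ZeroDivisionError):
            heritability(0.0, 0.0, 0.0)


class TestGeneticCorrelation:
    def test_identical_contrasts_unity(self):
        c = pm3_contrast(LegendreBasis(4))
        assert genetic_correlation(c, c, random_pd(4, 2)) == pytest.approx(1.0)

    def test_orthogonal_weights_zero_under_identity(self):
        from rrlact.basis import ContrastVector

        c1 = ContrastVector(np.array([0.0, 1.0, 0.0]), "POINT")
        c2 = ContrastVector(np.array([0.0, 0.0, 1.0]), "POINT")
        assert genetic_correlation(c1, c2, np.eye(3)) == pytest.approx(0.0)

    @settings(deadline=None, max_examples=30)
    @given(seed=st.integers(0, 10_000))
    def test_bounded_and_matches_loop_oracle(self, seed):
        basis = LegendreBasis(3)
        K = random_pd(3, seed)
        c1, c2 = pm1_contrast(basis), pm2_contrast(basis)
        r = genetic_correlation(c1, c2, K)
        assert -1.0 <= r <= 1.0
        cov = sum(c1.weights[i] * K[i, j] * c2.weights[j] for i in range(3) for j in range(3))
        expected = cov / np.sqrt(genetic_variance(c1, K) * genetic_variance(c2, K))
        assert r == pytest.approx(expected, rel=1e-10)

    def test_zero_variance_contrast_undefined(self):
        from rrlact.basis import ContrastVector

        c0 = ContrastVector(np.zeros(3), "POINT")
        with pytest.raises(ZeroDivisionError):
            genetic_correlation(c0, pm3_contrast(LegendreBasis(3)), np.eye(3))


class TestGeneticTrend:
    def test_constant_annual_means_flat(self):
        df = pd.DataFrame({"year": np.repeat(np.arange(2000, 2008), 5), "value": 0.3})
        res = genetic_trend(df)
        assert res.slope == pytest.approx(0.0, abs=1e-12)
        assert res.p_value > 0.9

    def test_exact_linear_trend_recovered(self):
        years = np.repeat(np.arange(2000, 2010), 3)
        df = pd.DataFrame({"year": years, "value": 0.01 * (years - 2000)})
        res = genetic_trend(df)
        assert res.slope == pytest.approx(0.01, rel=1e-10)
        assert res.p_value < 1e-10

    def test_too_few_years_rejected(self):
        df = pd.DataFrame({"year": [2000, 2000, 2001], "value": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="3 distinct"):
            genetic_trend(df)


class TestBuildReport:
    def test_scale_invariance_of_correlations(self):
        basis = LegendreBasis(3)
        K = random_pd(3, 5)
        r1 = build_report(K, K, 0.03, basis)
        r2 = build_report(4.0 * K, 4.0 * K, 0.12, basis)
        pd.testing.assert_frame_equal(r1.correlations, r2.correlations)

    def test_invariants(self):
        basis = LegendreBasis(3)
        rep = build_report(random_pd(3, 6), random_pd(3, 7), 0.05, basis)
        v = rep.variances
        assert ((v["h2"] >= 0) & (v["h2"] <= 1)).all()
        np.testing.assert_allclose(
            v["sigma2_p"], v[["sigma2_a", "sigma2_pe", "sigma2_e"]].sum(axis=1))
        C = rep.correlations.to_numpy()
        np.testing.assert_allclose(C, C.T)
        np.testing.assert_allclose(np.diag(C), 1.0)
        assert np.all(np.linalg.eigvalsh(C) > -1e-10)

    def test_h2_invariant_to_total_convention(self):
        basis = LegendreBasis(3)
        Ka, Kpe = random_pd(3, 8), random_pd(3, 9)
        h_sum = build_report(Ka, Kpe, 0.03, basis, total_convention="sum").variances["h2"]
        h_mean = build_report(Ka, Kpe, 0.03, basis, total_convention="mean").variances["h2"]
        np.testing.assert_allclose(h_sum, h_mean, rtol=1e-12)

    def test_phenotype_scale_equivariance(self):
        # multiplying yields by c multiplies all variances by c^2 and leaves
        # heritability and correlations unchanged
        basis = LegendreBasis(3)
        Ka, Kpe, se = random_pd(3, 10), random_pd(3, 11), 0.04
        c2 = 2.5**2
        r1 = build_report(Ka, Kpe, se, basis)
        r2 = build_report(c2 * Ka, c2 * Kpe, c2 * se, basis)
        np.testing.assert_allclose(r2.variances["sigma2_p"], c2 * r1.variances["sigma2_p"])
        np.testing.assert_allclose(r2.variances["h2"], r1.variances["h2"])
        pd.testing.assert_frame_equal(r1.correlations, r2.correlations)
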