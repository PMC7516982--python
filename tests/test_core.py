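"""The OEPIV distribution: density, distribution, quantile, moments, entropy."""

import numpy as np
import pytest
from scipy import integrate, special, stats

from oepiv import (OEPIVParams, oepiv_cdf, oepiv_hf, oepiv_median, oepiv_mode,
                   oepiv_moment_series, oepiv_moment_summary, oepiv_pdf,
                   oepiv_quantile, oepiv_raw_moment, oepiv_rvs, oepiv_sf,
                   order_statistic_pdf, renyi_entropy)


class TestExactValues:
    """Closed-form reductions: (1,1,1,1) is Exp(1); alpha=1 is Weibull."""

    def test_exponential_pdf(self, exp1):
        assert oepiv_pdf(0.5, exp1) == pytest.approx(np.exp(-0.5), rel=1e-12)

    def test_exponential_cdf_median(self, exp1):
        assert oepiv_cdf(np.log(2.0), exp1) == pytest.approx(0.5, abs=1e-12)
        assert oepiv_quantile(0.5, exp1) == pytest.approx(np.log(2.0), rel=1e-12)

    def test_cdf_boundary_zero(self, random_valid_params):
        for p in random_valid_params[:5]:
            assert oepiv_cdf(0.0, p) == 0.0
            assert oepiv_quantile(0.0, p) == 0.0

    def test_exponential_constant_hazard(self, exp1):
        x = np.array([0.1, 1.0, 5.0, 20.0])
        np.testing.assert_allclose(oepiv_hf(x, exp1), 1.0, rtol=1e-12)

    def test_exponential_moments(self, exp1):
        assert oepiv_raw_moment(1, exp1) == pytest.approx(1.0, rel=1e-9)
        assert oepiv_raw_moment(2, exp1) == pytest.approx(2.0, rel=1e-9)

    def test_weibull_mean(self):
        # alpha=1 reduces to Weibull(shape 1/a, scale theta*lam^-a)
        p = OEPIVParams(2.0, 0.5, 1.0, 1.0)
        assert oepiv_raw_moment(1, p) == pytest.approx(
            special.gamma(1.5) / np.sqrt(2.0), rel=1e-9)

    def test_exponential_moment_summary(self, exp1):
        s = oepiv_moment_summary(exp1)
        assert s.mean == pytest.approx(1.0, rel=1e-8)
        assert s.variance == pytest.approx(1.0, rel=1e-7)
        assert s.skewness == pytest.approx(2.0, rel=1e-6)
        assert s.excess_kurtosis == pytest.approx(6.0, rel=1e-5)

    def test_weibull_moment_summary(self):
        p = OEPIVParams(2.0, 0.5, 1.0, 1.0)
        s = oepiv_moment_summary(p)
        assert s.mean == pytest.approx(special.gamma(1.5) / np.sqrt(2.0), rel=1e-8)
        assert s.variance == pytest.approx((1.0 - np.pi / 4.0) / 2.0, rel=1e-7)

    def test_renyi_entropy_exponential(self, exp1):
        assert renyi_entropy(exp1, 2.0) == pytest.approx(np.log(2.0), abs=1e-8)
        assert renyi_entropy(exp1, 0.5) == pytest.approx(2.0 * np.log(2.0), abs=1e-8)

    def test_mode_weibull_shape2(self):
        # Weibull with shape 2 has mode scale/sqrt(2)
        assert oepiv_mode(OEPIVParams(1.0, 0.5, 1.0, 1.0)) == pytest.approx(
            np.sqrt(0.5), abs=1e-6)

    def test_mode_boundary_exponential(self, exp1):
        assert oepiv_mode(exp1) == 0.0

    def test_mode_matches_brute_force(self):
        p = OEPIVParams(2.0, 0.3, 1.0, 1.5)
        grid = np.linspace(1e-9, oepiv_quantile(0.999, p), 200001)
        brute = grid[np.argmax(oepiv_pdf(grid, p))]
        assert oepiv_mode(p) == pytest.approx(brute, abs=1e-5)


class TestValidation:
    @pytest.mark.parametrize("bad", [
        dict(lam=0.0), dict(a=-1.0), dict(theta=0.0), dict(alpha=-0.5),
        dict(lam=np.nan),
    ])
    def test_nonpositive_parameters_rejected(self, bad):
        kwargs = dict(lam=1.0, a=1.0, theta=1.0, alpha=1.0)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            OEPIVParams(**kwargs)

    def test_negative_x_rejected(self, exp1):
        with pytest.raises(ValueError):
            oepiv_pdf(-0.5, exp1)

    def test_quantile_domain(self, exp1):
        with pytest.raises(ValueError):
            oepiv_quantile(1.0, exp1)
        with pytest.raises(ValueError):
            oepiv_quantile(-0.1, exp1)

    def test_order_statistic_rank_domain(self, exp1):
        with pytest.raises(ValueError):
            order_statistic_pdf(0, 5, 1.0, exp1)
        with pytest.raises(ValueError):
            order_statistic_pdf(6, 5, 1.0, exp1)

    def test_rvs_requires_positive_n(self, exp1):
        with pytest.raises(ValueError):
            oepiv_rvs(0, exp1)

    def test_renyi_domain(self, exp1):
        with pytest.raises(ValueError):
            renyi_entropy(exp1, 1.0)


class TestDensityLimitsAtOrigin:
    def test_vanishes_when_inner_shape_above_one(self):
        assert oepiv_pdf(0.0, OEPIVParams(1.0, 0.5, 1.0, 1.0)) == 0.0

    def test_finite_limit_when_a_is_one(self):
        p = OEPIVParams(2.0, 1.0, 3.0, 1.5)
        assert oepiv_pdf(0.0, p) == pytest.approx(p.lam * p.alpha / (p.a * p.theta))

    def test_diverges_when_a_above_one(self):
        assert np.isinf(oepiv_pdf(0.0, OEPIVParams(1.0, 2.0, 1.0, 1.0)))


class TestProperties:
    def test_normalization(self, random_valid_params):
        # piecewise between quantiles: the support can span many decades
        probs = [1e-9, 0.01, 0.25, 0.5, 0.75, 0.99, 1 - 1e-9]
        for p in random_valid_params:
            knots = [0.0] + [float(oepiv_quantile(q, p)) for q in probs]
            total = sum(
                integrate.quad(lambda x: oepiv_pdf(x, p), a, b, limit=200)[0]
                for a, b in zip(knots[:-1], knots[1:]))
            total += integrate.quad(lambda x: oepiv_pdf(x, p), knots[-1],
                                    np.inf, limit=200)[0]
            assert total == pytest.approx(1.0, abs=1e-6)

    def test_quantile_roundtrip(self, random_valid_params):
        probs = np.array([1e-6, 0.01, 0.1, 0.25, 0.5, 0.75, 0.9, 0.99, 1 - 1e-6])
        for p in random_valid_params:
            np.testing.assert_allclose(
                oepiv_cdf(oepiv_quantile(probs, p), p), probs, atol=1e-9)

    def test_identities_sf_hf_pdf(self, random_valid_params):
        for p in random_valid_params[:8]:
            x = oepiv_quantile(np.linspace(0.02, 0.98, 50), p)
            np.testing.assert_allclose(oepiv_sf(x, p), 1.0 - oepiv_cdf(x, p),
                                       atol=1e-14)
            np.testing.assert_allclose(oepiv_hf(x, p),
                                       oepiv_pdf(x, p) / oepiv_sf(x, p),
                                       rtol=1e-10)

    def test_pdf_is_cdf_derivative(self, set_i, set_ii):
        h = 1e-6
        for p in (set_i, set_ii):
            x = oepiv_quantile(np.linspace(0.05, 0.95, 15), p)
            deriv = (oepiv_cdf(x + h, p) - oepiv_cdf(x - h, p)) / (2 * h)
            np.testing.assert_allclose(deriv, oepiv_pdf(x, p), rtol=1e-5)

    def test_weibull_reduction_cdf(self):
        # alpha=1: OEPIV(lam, a, theta, 1) == Weibull(shape 1/a, scale theta*lam^-a)
        rng = np.random.default_rng(3)
        x = np.geomspace(0.01, 30.0, 40)
        for _ in range(6):
            lam, a, theta = np.exp(rng.uniform(-1, 1, 3))
            p = OEPIVParams(lam, a, theta, 1.0)
            wb = stats.weibull_min(c=1.0 / a, scale=theta * lam ** (-a))
            np.testing.assert_allclose(oepiv_cdf(x, p), wb.cdf(x), atol=1e-12)

    def test_exponential_reduction_cdf(self, exp1):
        x = np.geomspace(0.01, 20.0, 30)
        np.testing.assert_allclose(oepiv_cdf(x, exp1), stats.expon.cdf(x),
                                   atol=1e-13)

    def test_alpha_one_odds_form(self):
        # the alpha=1 subfamily written through its own survival formula
        # (covers the exponential-Pareto and odds exponential-log-logistic cases)
        rng = np.random.default_rng(4)
        x = np.geomspace(0.05, 20.0, 30)
        for _ in range(5):
            lam, a, theta = np.exp(rng.uniform(-1, 1, 3))
            p = OEPIVParams(lam, a, theta, 1.0)
            direct = 1.0 - np.exp(-lam * (x / theta) ** (1.0 / a))
            np.testing.assert_allclose(oepiv_cdf(x, p), direct, atol=1e-12)

    def test_sampling_matches_cdf(self, set_i):
        x = oepiv_rvs(100_000, set_i, seed=123)
        assert np.all(x > 0)
        d = stats.ks_1samp(x, lambda t: oepiv_cdf(t, set_i)).statistic
        assert d < 0.01

    def test_sampling_reproducible(self, set_ii):
        a = oepiv_rvs(1, set_ii, seed=42)
        b = oepiv_rvs(1, set_ii, seed=42)
        assert a == b

    def test_empirical_median(self, set_i):
        x = oepiv_rvs(100_000, set_i, seed=5)
        assert np.median(x) == pytest.approx(oepiv_median(set_i), rel=0.02)

    def test_moment_inequality(self, random_valid_params):
        # kurtosis (non-excess) >= skewness^2 + 1 for every distribution
        for p in random_valid_params[:10]:
            s = oepiv_moment_summary(p)
            assert s.excess_kurtosis + 3.0 >= s.skewness**2 + 1.0 - 1e-8


class TestMomentSeries:
    def test_terminating_series_exponential(self, exp1):
        val, converged = oepiv_moment_series(1, exp1, k_max=2)
        assert converged
        assert val == pytest.approx(1.0, rel=1e-12)

    def test_terminating_series_hand_terms(self, exp1):
        # a*r = 1: k=0 term e*Gamma(2,1) = 2, k=1 term -e*Gamma(1,1) = -1
        k0 = np.e * special.gammaincc(2, 1) * special.gamma(2)
        k1 = -np.e * special.gammaincc(1, 1) * special.gamma(1)
        assert k0 == pytest.approx(2.0, rel=1e-12)
        assert k1 == pytest.approx(-1.0, rel=1e-12)
        val, _ = oepiv_moment_series(1, exp1, k_max=3)
        assert val == pytest.approx(k0 + k1, rel=1e-12)

    def test_integer_ar_matches_quadrature(self):
        p = OEPIVParams(1.5, 2.0, 0.8, 0.9)  # a*r = 2, series terminates
        val, converged = oepiv_moment_series(1, p, k_max=4)
        assert converged
        assert val == pytest.approx(oepiv_raw_moment(1, p), rel=1e-8)

    def test_convergent_series_matches_quadrature(self, random_valid_params):
        # wherever the series reports convergence it must agree with quadrature;
        # integer a*r guarantees termination, random parameters may or may not
        cases = [OEPIVParams(0.7, 1.0, 1.3, 0.8), OEPIVParams(1.2, 3.0, 0.5, 1.1),
                 OEPIVParams(2.0, 2.0, 1.0, 0.6)] + list(random_valid_params[:8])
        checked = 0
        for p in cases:
            val, converged = oepiv_moment_series(1, p, k_max=300)
            if converged:
                assert val == pytest.approx(oepiv_raw_moment(1, p), rel=1e-4)
                checked += 1
        assert checked >= 3

    def test_nonconvergence_is_flagged_not_raised(self):
        p = OEPIVParams(1.0, 2.5, 1.0, 0.4)  # non-integer a*r
        val, converged = oepiv_moment_series(1, p, k_max=30)
        assert isinstance(val, float)
        assert isinstance(converged, bool)


class TestOrderStatistics:
    def test_single_observation_is_parent_pdf(self, set_i):
        y = np.geomspace(0.05, 5.0, 20)
        np.testing.assert_allclose(order_statistic_pdf(1, 1, y, set_i),
                                   oepiv_pdf(y, set_i), rtol=1e-12)

    def test_normalization(self, set_i):
        val, _ = integrate.quad(lambda y: order_statistic_pdf(2, 5, y, set_i),
                                0, np.inf, limit=300)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_against_simulation(self, exp1):
        # 3rd order statistic of samples of size 7: compare the implied CDF
        # (Beta(k, n-k+1) of the parent CDF) with the empirical distribution
        rng = np.random.default_rng(10)
        samples = np.sort(oepiv_rvs(7 * 20_000, exp1, seed=rng).reshape(20_000, 7),
                          axis=1)
        third = samples[:, 2]
        cdf = lambda y: stats.beta.cdf(oepiv_cdf(y, exp1), 3, 5)
        d = stats.ks_1samp(third, cdf).statistic
        # KS 1% critical value for n=20000 is ~0.0115
        assert d < 0.0115


def test_renyi_entropy_quadrature_stability(set_ii):
    # value stable under refinement of the split point
    v = renyi_entropy(set_ii, 2.0)
    split_alt = float(oepiv_quantile(0.99, set_ii))
    v1, _ = integrate.quad(lambda x: oepiv_pdf(x, set_ii) ** 2, 0, split_alt,
                           limit=300)
    v2, _ = integrate.quad(lambda x: oepiv_pdf(x, set_ii) ** 2, split_alt,
                           np.inf, limit=300)
    assert v == pytest.approx(np.log(v1 + v2) / (1 - 2.0), abs=1e-6)


class TestHypothesisInvariants:
    """Randomized invariants over the parameter space (derandomized runs)."""

    hypothesis = pytest.importorskip("hypothesis")
    from hypothesis import given, settings, strategies as st

    param_floats = st.floats(0.05, 20.0)
    prob_floats = st.floats(1e-6, 1 - 1e-6)

    @staticmethod
    def _params(lam, a, theta, alpha):
        return OEPIVParams(lam, a, theta, alpha)

    @given(lam=param_floats, a=param_floats, theta=param_floats,
           alpha=param_floats, p=prob_floats)
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_quantile_roundtrip(self, lam, a, theta, alpha, p):
        params = self._params(lam, a, theta, alpha)
        assert oepiv_cdf(oepiv_quantile(p, params), params) == pytest.approx(
            p, abs=1e-9)

    @given(lam=param_floats, a=param_floats, theta=param_floats,
           alpha=param_floats, p=prob_floats)
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_complement_and_hazard_identities(self, lam, a, theta, alpha, p):
        params = self._params(lam, a, theta, alpha)
        x = float(oepiv_quantile(p, params))
        assert oepiv_sf(x, params) == pytest.approx(1.0 - oepiv_cdf(x, params),
                                                    abs=1e-12)
        if x > 0:
            assert oepiv_hf(x, params) * oepiv_sf(x, params) == pytest.approx(
                float(oepiv_pdf(x, params)), rel=1e-9)

    @given(lam=param_floats, a=param_floats, theta=param_floats,
           alpha=param_floats)
    @settings(derandomize=True, max_examples=40, deadline=None)
    def test_cdf_monotone(self, lam, a, theta, alpha):
        params = self._params(lam, a, theta, alpha)
        x = oepiv_quantile(np.linspace(0.001, 0.999, 30), params)
        c = oepiv_cdf(x, params)
        assert np.all(np.diff(c) >= 0)


def test_params_dict_roundtrip(set_i):
    d = set_i.to_dict()
    assert set(d) == {"lambda", "a", "theta", "alpha"}
    assert OEPIVParams.from_dict(d) == set_i
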