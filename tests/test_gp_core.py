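"""Correlation functions, covariance assembly, simulation and kriging."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mossmap import gp_core as g

from _oracles import bessel_k_integral, conditional_gaussian_brute


class TestCorrelationFunctions:
    def test_matern_is_one_at_zero_distance(self):
        assert g.matern_correlation(0.0, g.MaternParams(1.0, 2.0, 1.0)) == 1.0

    def test_matern_half_smoothness_is_exponential_closed_form(self):
        # kappa = 1/2 reduces to exp(-u/phi)
        val = g.matern_correlation(2.0, g.MaternParams(1.0, 2.0, 0.5))
        assert val == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_matern_kappa_one_matches_bessel_integral_oracle(self):
        # rho(1; phi=1, kappa=1) = K_1(1), checked against the integral representation
        oracle = bessel_k_integral(1.0, 1.0)
        assert oracle == pytest.approx(0.6019, abs=5e-4)
        val = g.matern_correlation(1.0, g.MaternParams(1.0, 1.0, 1.0))
        assert val == pytest.approx(oracle, rel=1e-9)

    def test_matern_equals_exponential_for_half_smoothness_on_grid(self):
        u = np.linspace(0.0, 20.0, 100)
        m = g.matern_correlation(u, g.MaternParams(1.0, 3.0, 0.5))
        e = g.exponential_correlation(u, g.ExponentialParams(1.0, 3.0))
        np.testing.assert_allclose(m, e, atol=1e-10)

    @pytest.mark.parametrize("kappa", [0.5, 1.0, 2.5])
    def test_correlations_decreasing_and_bounded(self, kappa):
        u = np.linspace(0.0, 30.0, 200)
        rho = np.asarray(g.matern_correlation(u, g.MaternParams(1.0, 2.0, kappa)))
        assert np.all(rho > 0) and np.all(rho <= 1.0)
        assert np.all(np.diff(rho) < 0)

    def test_exponential_closed_form_values(self):
        p = g.ExponentialParams(1.0, 4.0)
        assert g.exponential_correlation(0.0, p) == 1.0
        assert g.exponential_correlation(4.0, p) == pytest.approx(np.exp(-1))
        # distance -psi ln(0.75) gives exactly the 0.75 masking-rule cutoff
        assert g.exponential_correlation(-4.0 * np.log(0.75), p) == pytest.approx(0.75)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            g.matern_correlation(-1.0, g.MaternParams(1.0, 1.0))
        with pytest.raises(ValueError):
            g.exponential_correlation(-0.5, g.ExponentialParams(1.0, 1.0))

    @pytest.mark.parametrize("bad", [(-1.0, 1.0), (1.0, 0.0), (0.0, 2.0)])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            g.ExponentialParams(*bad)
        with pytest.raises(ValueError):
            g.MaternParams(*bad)


class TestBuildCovariance:
    def test_single_location(self):
        cov = g.build_covariance([(0.0, 0.0)], g.ExponentialParams(2.0, 1.0))
        np.testing.assert_allclose(cov, [[2.0]])

    def test_two_locations_off_diagonal(self):
        p = g.ExponentialParams(1.5, 2.0)
        cov = g.build_covariance([(0, 0), (0, 3.0)], p)
        assert cov[0, 1] == pytest.approx(1.5 * np.exp(-1.5))
        assert cov[0, 0] == pytest.approx(1.5)

    def test_nugget_on_diagonal_only(self):
        cov = g.build_covariance([(0, 0), (1, 0)], g.ExponentialParams(1.0, 1.0), nugget=0.3)
        assert cov[0, 0] == pytest.approx(1.3)
        assert cov[0, 1] == pytest.approx(np.exp(-1.0))

    @pytest.mark.parametrize("params", [g.MaternParams(2.0, 3.0), g.ExponentialParams(0.7, 5.0)])
    def test_matches_brute_force_double_loop(self, rng, params):
        locs = rng.uniform(0, 10, (5, 2))
        cov = g.build_covariance(locs, params, nugget=0.1)
        for i in range(5):
            for k in range(5):
                u = np.hypot(*(locs[i] - locs[k]))
                if isinstance(params, g.MaternParams):
                    expect = params.variance * g.matern_correlation(u, params)
                else:
                    expect = params.variance * g.exponential_correlation(u, params)
                if i == k:
                    expect += 0.1
                assert cov[i, k] == pytest.approx(expect, rel=1e-12)

    def test_duplicate_locations_handled_by_jitter_policy(self):
        # duplicates with zero nugget make the matrix singular; the documented
        # policy retries once with diagonal jitter instead of failing silently
        locs = [(1.0, 1.0), (1.0, 1.0)]
        cov = g.build_covariance(locs, g.ExponentialParams(1.0, 1.0))
        chol = g.cholesky_with_jitter(cov)
        assert np.all(np.isfinite(chol))
        g.cholesky_with_jitter(g.build_covariance(locs, g.ExponentialParams(1.0, 1.0), nugget=0.1))


class TestSimulateField:
    def test_same_seed_identical(self, rng):
        locs = rng.uniform(0, 5, (8, 2))
        p = g.MaternParams(1.0, 2.0)
        a = g.simulate_field(locs, p, seed=9)
        b = g.simulate_field(locs, p, seed=9)
        np.testing.assert_array_equal(a.values, b.values)

    def test_marginal_moments(self):
        # 2000 replicate draws at one location: variance near 1.5, mean near 0
        draws = np.array([
            g.simulate_field([(0.0, 0.0)], g.ExponentialParams(1.5, 1.0), seed=s).values[0]
            for s in range(2000)
        ])
        se_var = 1.5 * np.sqrt(2.0 / (len(draws) - 1))
        assert abs(draws.var(ddof=1) - 1.5) < 3 * se_var
        assert abs(draws.mean()) < 3 * np.sqrt(1.5 / len(draws))

    def test_empirical_covariance_converges(self, rng):
        locs = rng.uniform(0, 4, (4, 2))
        p = g.ExponentialParams(1.0, 2.0)
        target = g.build_covariance(locs, p)
        chol = g.cholesky_with_jitter(target)
        z = np.random.default_rng(1).standard_normal((4, 6000))
        draws = chol @ z
        errs = []
        for m in (500, 6000):
            emp = np.cov(draws[:, :m])
            errs.append(np.linalg.norm(emp - target))
        assert errs[1] < errs[0]


class TestConditionalMean:
    def test_interpolates_observations_without_nugget(self, rng):
        locs = rng.uniform(0, 6, (5, 2))
        p = g.MaternParams(1.0, 2.0)
        f = g.simulate_field(locs, p, seed=3)
        mean = g.conditional_mean_field(f, locs, p)
        np.testing.assert_allclose(mean, f.values, atol=1e-5)

    def test_reverts_to_prior_mean_far_away(self, rng):
        locs = rng.uniform(0, 2, (4, 2))
        p = g.ExponentialParams(1.0, 1.0)
        f = g.simulate_field(locs, p, seed=5)
        mean = g.conditional_mean_field(f, [(500.0, 500.0)], p)
        assert abs(mean[0]) < 1e-8

    def test_matches_dense_joint_gaussian_oracle(self, rng):
        # 3 observed + 2 targets against the explicit block formula
        locs = rng.uniform(0, 5, (5, 2))
        p = g.ExponentialParams(0.8, 3.0)
        joint = g.build_covariance(locs, p)
        obs_vals = rng.normal(size=3)
        mean_o, cov_o = conditional_gaussian_brute(joint, [0, 1, 2], [3, 4], obs_vals)
        mean, var = g.conditional_gaussian(locs[:3], obs_vals, locs[3:], p)
        np.testing.assert_allclose(mean, mean_o, atol=1e-6)
        np.testing.assert_allclose(var, np.diag(cov_o), atol=1e-6)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(u1=st.floats(0.0, 50.0), u2=st.floats(0.0, 50.0),
       scale=st.floats(0.1, 20.0))
def test_exponential_correlation_monotone_property(u1, u2, scale):
    p = g.ExponentialParams(1.0, scale)
    lo, hi = sorted([u1, u2])
    assert g.exponential_correlation(hi, p) <= g.exponential_correlation(lo, p)
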