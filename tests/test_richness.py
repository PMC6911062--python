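"""Spline basis, linear predictors, richness fitting and mu prediction."""

import numpy as np
import pandas as pd
import pytest

from mossmap import region, richness, synthetic
from mossmap._mcml import MCSettings
from mossmap.gp_core import ExponentialParams
from mossmap.richness import (
    CSDModelParams,
    RichnessFit,
    RichnessRecord,
    RSDModelParams,
    SplineSpec,
    linear_predictor_csd,
    linear_predictor_rsd,
    spline_basis,
)


class TestSplineBasis:
    def test_partition_of_unity(self):
        spec = SplineSpec()
        years = np.arange(1985, 2010)
        basis = spline_basis(years, spec)
        np.testing.assert_allclose(basis.sum(axis=1), 1.0, atol=1e-12)
        assert basis.shape[1] == spec.n_basis

    def test_second_derivative_continuous_at_knot(self):
        # C2 continuity across the interior knot at 2000: the second
        # derivative approaching from both sides agrees to 1e-6
        from scipy.interpolate import BSpline

        spec = SplineSpec()
        coefs = np.sin(np.arange(spec.n_basis))  # arbitrary smooth combination
        spl = BSpline(spec.knot_vector(), coefs, spec.degree)
        d2 = spl.derivative(2)
        assert abs(d2(2000 - 1e-6) - d2(2000 + 1e-6)) < 1e-5
        # and the basis evaluated through the package agrees with the spline
        years = np.array([1992.5, 2000.0, 2005.5])
        np.testing.assert_allclose(spline_basis(years, spec) @ coefs, spl(years), atol=1e-12)

    def test_equal_coefficients_give_flat_function(self):
        spec = SplineSpec()
        years = np.arange(1986, 2009)
        f = spline_basis(years, spec) @ np.full(spec.n_basis, 2.5)
        np.testing.assert_allclose(f, 2.5, atol=1e-12)

    def test_year_outside_boundary_rejected(self):
        with pytest.raises(ValueError):
            spline_basis([1980], SplineSpec())
        with pytest.raises(ValueError):
            spline_basis([2012], SplineSpec())

    def test_knots_must_increase(self):
        with pytest.raises(ValueError):
            SplineSpec(knots=(1995, 1990))


@pytest.fixture
def csd_params():
    return CSDModelParams(
        beta0=0.5, beta1=0.6, beta2=-0.3, beta3=0.9, beta4=1.9, gamma=0.4,
        spline_coefs=np.zeros(SplineSpec().n_basis - 1),
        field=ExponentialParams(0.15, 5.0), nugget=0.05,
    )


class TestLinearPredictors:
    def test_csd_reduces_to_intercept(self, csd_params):
        p = CSDModelParams(**{**csd_params.__dict__, "gamma": 0.0})
        rec = RichnessRecord((1.0, 1.0), 1997, 1, 3, "CSD")
        assert linear_predictor_csd(rec, (0, 0, 0), 0.0, p) == pytest.approx(p.beta0)

    def test_doubling_collectors_adds_beta4_log2(self, csd_params):
        rec1 = RichnessRecord((1.0, 1.0), 1997, 1, 3, "CSD")
        rec2 = RichnessRecord((1.0, 1.0), 1997, 2, 3, "CSD")
        d = (linear_predictor_csd(rec2, (0.2, 0.4, 0.6), 0.1, csd_params)
             - linear_predictor_csd(rec1, (0.2, 0.4, 0.6), 0.1, csd_params))
        assert d == pytest.approx(csd_params.beta4 * np.log(2))

    def test_csd_matches_term_by_term_sum(self, csd_params):
        spec = SplineSpec()
        coefs = np.linspace(-0.2, 0.3, spec.n_basis - 1)
        p = CSDModelParams(**{**csd_params.__dict__, "spline_coefs": coefs})
        rec = RichnessRecord((2.0, 3.0), 2001, 3, 5, "CSD")
        W, V, F, shat = 0.3, 0.7, 0.2, -0.5
        hand = (p.beta0 + p.beta1 * W + p.beta2 * V + p.beta3 * F
                + p.beta4 * np.log(3)
                + spline_basis([2001], spec)[0, 1:] @ coefs
                + p.gamma * shat)
        assert linear_predictor_csd(rec, (W, V, F), shat, p) == pytest.approx(hand)

    def test_rsd_time_centering(self):
        p = RSDModelParams(beta0=1.0, beta1=0.0, beta2=0.0, beta3=0.0, beta5=-0.1,
                           field=ExponentialParams(0.1, 13.0), nugget=0.04)
        rec97 = RichnessRecord((1, 1), 1997, 1, 2, "RSD")
        rec99 = RichnessRecord((1, 1), 1999, 1, 2, "RSD")
        assert linear_predictor_rsd(rec97, (0, 0, 0), p) == pytest.approx(1.0)
        assert linear_predictor_rsd(rec99, (0, 0, 0), p) == pytest.approx(1.0 - 0.2)

    def test_rsd_matches_hand_sum(self):
        p = RSDModelParams(beta0=1.5, beta1=-0.3, beta2=0.4, beta3=0.2, beta5=-0.08,
                           field=ExponentialParams(0.1, 13.0), nugget=0.04)
        rec = RichnessRecord((2, 2), 1998, 1, 4, "RSD")
        hand = 1.5 - 0.3 * 0.1 + 0.4 * 0.9 + 0.2 * 0.5 - 0.08 * 1
        assert linear_predictor_rsd(rec, (0.1, 0.9, 0.5), p) == pytest.approx(hand)

    def test_invalid_collectors_rejected(self, csd_params):
        with pytest.raises(ValueError):
            RichnessRecord((1, 1), 1997, 0, 3, "CSD")


def _toy_fit(grid, theta, beta, names, spline=None, source="RSD", cells=None):
    """Hand-built RichnessFit for prediction-formula checks."""
    cells = np.array([[0.5, 0.5]]) if cells is None else cells
    n = len(cells)
    return RichnessFit(
        source=source, estimates={}, ci_low={}, ci_high={},
        column_names=names, beta=np.asarray(beta, float), theta=np.asarray(theta, float),
        latent_mean=np.zeros(n), latent_cov=np.zeros((n, n)),
        record_cells=cells, spline=spline, grid=grid, loglik=0.0, settings={},
        wald_cov=np.zeros((len(beta) + 3, len(beta) + 3)),
    )


class TestPredictMu:
    def test_no_latent_limit_is_plugin_exponential(self, small_grid, rng):
        vals = {n: rng.uniform(0, 1, small_grid.n_cells) for n in "WVF"}
        surfaces = {n: region.CovariateSurface(grid=small_grid, name=n, values=vals[n])
                    for n in "WVF"}
        beta = [1.2, -0.3, 0.4, 0.2, -0.08]
        fit = _toy_fit(small_grid, [-np.inf, 0.0, -np.inf], beta,
                       ["beta0", "beta1", "beta2", "beta3", "beta5"])
        surf = richness.predict_mu(fit, small_grid, 1998, None, surfaces)
        eta = (beta[0] + beta[1] * vals["W"] + beta[2] * vals["V"]
               + beta[3] * vals["F"] + beta[4] * 1.0)
        np.testing.assert_allclose(surf.mean, np.exp(eta), rtol=1e-12)
        np.testing.assert_array_equal(surf.se, np.zeros(small_grid.n_cells))

    def test_collector_ratio_is_power_of_beta4(self, small_grid, rng):
        vals = {n: rng.uniform(0, 1, small_grid.n_cells) for n in "WVF"}
        surfaces = {n: region.CovariateSurface(grid=small_grid, name=n, values=vals[n])
                    for n in "WVF"}
        spec = SplineSpec()
        beta4 = 1.9
        beta = np.r_[[0.5, 0.6, -0.3, 0.9, beta4], np.zeros(spec.n_basis - 1)]
        names = ["beta0", "beta1", "beta2", "beta3", "beta4"] + [
            f"spline_{j+1}" for j in range(spec.n_basis - 1)
        ]
        fit = _toy_fit(small_grid, [-np.inf, 0.0, -np.inf], beta, names,
                       spline=spec, source="CSD")
        fit.gamma_dropped = True
        s1 = richness.predict_mu(fit, small_grid, 1998, 1, surfaces)
        s2 = richness.predict_mu(fit, small_grid, 1998, 2, surfaces)
        np.testing.assert_allclose(s2.mean / s1.mean, 2.0**beta4, rtol=1e-10)

    def test_single_cell_lognormal_moments_match_sampling_oracle(self):
        # one observed record with known T posterior; the predictive mean at
        # the record cell must equal the lognormal closed form E exp(eta+U)
        grid = region.make_grid((0, 0, 1, 1), 1.0)
        surfaces = {n: region.CovariateSurface(grid=grid, name=n, values=np.array([0.0]))
                    for n in "WVF"}
        nu2, psi, tau2 = 0.4, 5.0, 1e-12
        fit = _toy_fit(grid, np.log([nu2, psi, tau2]), [1.0, 0, 0, 0, 0.0],
                       ["beta0", "beta1", "beta2", "beta3", "beta5"])
        m_post, v_post = 0.3, 0.1
        fit.latent_mean = np.array([m_post])
        fit.latent_cov = np.array([[v_post]])
        surf = richness.predict_mu(fit, grid, 1997, None, surfaces)
        # at the record cell with tau2 ~ 0: U | y has mean m_post, var v_post
        rng = np.random.default_rng(0)
        draws = np.exp(1.0 + rng.normal(m_post, np.sqrt(v_post), 400_000))
        assert surf.mean[0] == pytest.approx(np.exp(1.0 + m_post + v_post / 2), rel=1e-6)
        assert surf.mean[0] == pytest.approx(draws.mean(), rel=0.01)
        se_oracle = draws.std()
        assert surf.se[0] == pytest.approx(se_oracle, rel=0.02)

    def test_monotone_in_each_covariate(self, small_grid):
        # raising a covariate cell-wise moves the mean in the coefficient's direction
        base = {n: np.full(small_grid.n_cells, 0.5) for n in "WVF"}
        surfaces = {n: region.CovariateSurface(grid=small_grid, name=n, values=base[n])
                    for n in "WVF"}
        beta = [1.0, -0.3, 0.4, 0.2, 0.0]
        fit = _toy_fit(small_grid, [-np.inf, 0.0, -np.inf], beta,
                       ["beta0", "beta1", "beta2", "beta3", "beta5"])
        ref = richness.predict_mu(fit, small_grid, 1997, None, surfaces).mean
        for n, coef in (("W", -0.3), ("V", 0.4), ("F", 0.2)):
            bumped = dict(surfaces)
            bumped[n] = region.CovariateSurface(grid=small_grid, name=n,
                                                values=np.full(small_grid.n_cells, 0.7))
            out = richness.predict_mu(fit, small_grid, 1997, None, bumped).mean
            assert np.all((out > ref) == (coef > 0))


class TestFitRichness:
    def test_zero_shat_reproduces_unadjusted_fit(self, desk_scenario):
        recs = desk_scenario.records
        covs = desk_scenario.covariates
        settings = MCSettings(n_samples=150, info_samples=200, max_refresh=2, seed=3)
        from mossmap.lgcp import SHatSurface

        shat0 = SHatSurface(grid=desk_scenario.grid,
                            values=np.zeros(desk_scenario.grid.n_cells))
        fit_adj = richness.fit_richness(recs, covs, shat0, "CSD", mc_settings=settings)
        assert fit_adj.gamma_dropped
        assert fit_adj.estimates["gamma"] == 0.0
        fit_direct = richness.fit_richness(recs, covs, shat0, "CSD", mc_settings=settings)
        for k in fit_adj.estimates:
            assert fit_adj.estimates[k] == fit_direct.estimates[k]

    def test_rsd_fit_recovers_signs_and_brackets(self, desk_scenario):
        cfg = desk_scenario.config
        fit = richness.fit_richness(desk_scenario.records, desk_scenario.covariates,
                                    None, "RSD",
                                    mc_settings=MCSettings(n_samples=150, max_refresh=2, seed=9))
        for k in fit.estimates:
            assert fit.ci_low[k] <= fit.estimates[k] <= fit.ci_high[k]
        # point estimate of the intercept lands within a broad bracket of truth
        assert abs(fit.estimates["beta0"] - cfg.rsd_beta[0]) < 1.5

    def test_constant_covariate_warns_collinear(self, desk_scenario):
        covs = dict(desk_scenario.covariates)
        grid = desk_scenario.grid
        covs["V"] = region.CovariateSurface(grid=grid, name="V",
                                            values=np.full(grid.n_cells, 0.5))
        with pytest.warns(UserWarning, match="collinear"):
            richness.fit_richness(desk_scenario.records, covs, None, "RSD",
                                  mc_settings=MCSettings(n_samples=100, max_refresh=1, seed=2))


def test_records_io_roundtrip(tmp_path, desk_scenario):
    path = tmp_path / "records.csv"
    desk_scenario.records.to_csv(path, index=False)
    df = richness.read_records(path)
    assert set(df["source"]) == {"CSD", "RSD"}
    np.testing.assert_allclose(df["x"], desk_scenario.records["x"])
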