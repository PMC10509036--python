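"""Hierarchical model: transforms, design construction, Gibbs correctness."""

import numpy as np
import pandas as pd
import pytest

from ccitrend.model import (Design, MCMCSpec, ModelSpec, PosteriorDraws,
                            build_design, fit, inv_logit, load_draws, logit,
                            log_density_per_obs, save_draws)


class TestLogit:
    def test_closed_forms(self):
        assert logit(0.5) == pytest.approx(0.0, abs=1e-15)
        assert inv_logit(0.0) == pytest.approx(0.5, abs=1e-15)
        assert logit(1.0, eps=0.001) == pytest.approx(np.log(0.999 / 0.001),
                                                      abs=1e-12)

    def test_round_trip_interior(self, rng):
        p = rng.uniform(0.01, 0.99, size=50)
        np.testing.assert_allclose(inv_logit(logit(p)), p, atol=1e-12)

    def test_output_strictly_inside_unit_interval(self):
        x = np.array([-800.0, -30.0, 0.0, 30.0, 800.0])
        q = inv_logit(x)
        assert np.all(q > 0) and np.all(q < 1)

    @pytest.mark.parametrize("bad", [-0.1, 1.1, np.nan])
    def test_domain_checked(self, bad):
        with pytest.raises(ValueError):
            logit(bad)

    def test_eps_validated(self):
        with pytest.raises(ValueError):
            logit(0.5, eps=0.5)


def _mini_panel(levels, stratum_type, countries=("C1",), years=(2000, 2005, 2010)):
    rows = []
    rng = np.random.default_rng(0)
    for c in countries:
        for y in years:
            for lvl in levels:
                rows.append({"country_id": c, "region_id": "R1", "year": y,
                             "stratum_type": stratum_type, "stratum_level": lvl,
                             "cci": rng.uniform(0.3, 0.8)})
    return pd.DataFrame(rows)


def _mini_cov(countries=("C1",), years=range(2000, 2031)):
    # sdi follows a saturating curve so it is never collinear with year
    rows = [{"country_id": c, "year": y,
             "sdi": 0.4 + 0.3 / (1.0 + np.exp(-(y - 2010) / 4.0)),
             "ggdph": 3.0, "gdpc": 1000.0 + 10 * (y - 2000)}
            for c in countries for y in years]
    return pd.DataFrame(rows)


class TestBuildDesign:
    def test_residence_dummy_coding(self):
        panel = _mini_panel(["national", "urban", "rural"], "residence")
        panel.loc[panel.stratum_level == "national", "stratum_type"] = "national"
        spec = ModelSpec(variant="residence", covariates=("sdi",),
                         mcmc=MCMCSpec(seed=0))
        d = build_design(panel, _mini_cov(), spec)
        dummies = [c for c in d.col_names if c.startswith("stratum[")]
        assert dummies == ["stratum[urban]", "stratum[rural]"]  # k-1, ref national

    def test_wealth_dummy_coding_reference_q1(self):
        panel = _mini_panel(["Q1", "Q2", "Q3", "Q4", "Q5"], "wealth")
        spec = ModelSpec(variant="wealth", covariates=("sdi",),
                         mcmc=MCMCSpec(seed=0))
        d = build_design(panel, _mini_cov(), spec)
        dummies = [c for c in d.col_names if c.startswith("stratum[")]
        assert dummies == [f"stratum[Q{i}]" for i in (2, 3, 4, 5)]
        assert d.stratum_reference == "Q1"

    def test_single_country_reduces_to_plain_regression(self):
        panel = _mini_panel(["national"], "national",
                            years=tuple(range(2000, 2012)))
        spec = ModelSpec(variant="national", covariates=("sdi", "gdpc"),
                         mcmc=MCMCSpec(seed=0))
        d = build_design(panel, _mini_cov(), spec)
        assert d.col_names == ["intercept", "year_c", "sdi", "gdpc"]
        assert not d.hierarchical

    def test_covariate_gaps_reported(self):
        panel = _mini_panel(["national"], "national", years=(2000, 2019))
        cov = _mini_cov(years=[2000])  # 2019 missing
        spec = ModelSpec(variant="national", covariates=("sdi",),
                         mcmc=MCMCSpec(seed=0))
        with pytest.raises(ValueError, match=r"\('C1', 2019\)"):
            build_design(panel, cov, spec)

    def test_collinear_columns_rejected(self):
        panel = _mini_panel(["national"], "national")
        spec = ModelSpec(variant="national", covariates=("sdi", "sdi"),
                         mcmc=MCMCSpec(seed=0))
        with pytest.raises(ValueError, match="VIF"):
            build_design(panel, _mini_cov(), spec)

    def test_row_permutation_invariance(self, small_bundle):
        spec = ModelSpec(mcmc=MCMCSpec(seed=0))
        d1 = build_design(small_bundle.panel, small_bundle.covariates, spec)
        shuffled = small_bundle.panel.sample(frac=1.0, random_state=5)
        d2 = build_design(shuffled, small_bundle.covariates, spec)
        np.testing.assert_array_equal(d1.X, d2.X)
        np.testing.assert_array_equal(d1.y, d2.y)


class TestFit:
    def test_reproducible_given_seed(self, small_bundle):
        spec = ModelSpec(mcmc=MCMCSpec(chains=2, iterations=200, burn_in=100,
                                       seed=42))
        d = build_design(small_bundle.panel, small_bundle.covariates, spec)
        a, b = fit(d, spec), fit(d, spec)
        np.testing.assert_array_equal(a.beta, b.beta)
        np.testing.assert_array_equal(a.tau2, b.tau2)

    def test_seed_required(self, small_bundle):
        spec = ModelSpec(mcmc=MCMCSpec(chains=2, iterations=200, burn_in=100))
        d = build_design(small_bundle.panel, small_bundle.covariates, spec)
        with pytest.raises(ValueError, match="seed"):
            fit(d, spec)

    def test_gls_closed_form_no_hierarchy(self):
        """Flat prior + known tau + no hierarchy: the posterior is exactly
        N(OLS, tau^2 (X'X)^-1); Gibbs must match within Monte-Carlo error."""
        panel = _mini_panel(["national"], "national",
                            years=tuple(range(2000, 2020)))
        spec = ModelSpec(variant="national", covariates=(),
                         beta_prior_sd=1e6,
                         mcmc=MCMCSpec(chains=4, iterations=2500, burn_in=500,
                                       seed=3))
        d = build_design(panel, _mini_cov(), spec)
        tau2 = 0.04
        draws = fit(d, spec, fixed_tau2=tau2)
        XtX_inv = np.linalg.inv(d.X.T @ d.X)
        beta_gls = XtX_inv @ d.X.T @ d.y
        post = draws.stacked("beta")
        mc_se = np.sqrt(np.diag(tau2 * XtX_inv) / post.shape[0])
        np.testing.assert_allclose(post.mean(axis=0), beta_gls,
                                   atol=float(5 * mc_se.max()) + 1e-4)
        np.testing.assert_allclose(post.std(axis=0),
                                   np.sqrt(np.diag(tau2 * XtX_inv)), rtol=0.1)

    def test_zero_variance_response_degenerate_fit(self):
        panel = _mini_panel(["national"], "national",
                            years=tuple(range(2000, 2012)))
        panel["cci"] = 0.6
        spec = ModelSpec(variant="national", covariates=(),
                         mcmc=MCMCSpec(chains=2, iterations=1000, burn_in=500,
                                       seed=9))
        d = build_design(panel, _mini_cov(), spec)
        draws = fit(d, spec)
        b = draws.stacked("beta")
        assert b[:, 0].mean() == pytest.approx(logit(0.6), abs=0.01)
        assert abs(b[:, 1].mean()) < 0.01  # no trend in a flat series

    def test_predictions_inside_unit_interval(self, small_fit, small_bundle):
        from ccitrend.projection import predict_country

        g = predict_country(small_fit, small_bundle.covariates,
                            small_fit.design.countries[0],
                            [2000, 2015, 2030], "national")
        assert np.all(g > 0) and np.all(g < 1)

    def test_save_load_round_trip(self, small_fit, tmp_path):
        p = tmp_path / "draws.npz"
        save_draws(small_fit, p)
        back = load_draws(p)
        np.testing.assert_array_equal(back.beta, small_fit.beta)
        assert back.design.col_names == small_fit.design.col_names
        assert back.spec.mcmc.seed == small_fit.spec.mcmc.seed
        assert back.design.covariate_stats == small_fit.design.covariate_stats


class TestDeviance:
    def _design_1obs(self, y=0.3):
        return Design(
            y=np.array([y]), X=np.array([[1.0]]), col_names=["intercept"],
            prior_sd=np.array([10.0]), country_idx=np.array([0]),
            countries=["C1"], region_of_country=np.array([0]), regions=["R1"],
            variant="national", stratum_reference="national",
            year_center=2015.0, year_scale=10.0, covariate_stats={},
            obs_stratum=np.array(["national"]), obs_year=np.array([2010.0]),
            obs_cci=np.array([inv_logit(y)]))

    def _draws_const(self, design, beta0, tau2, n=120):
        shape = (2, n // 2)
        return PosteriorDraws(
            beta=np.full(shape + (1,), beta0), u=np.zeros(shape + (1,)),
            v=np.zeros(shape + (1,)), tau2=np.full(shape, tau2),
            sigma2_country=np.ones(shape), sigma2_region=np.ones(shape),
            design=design, spec=ModelSpec(variant="national", covariates=(),
                                          mcmc=MCMCSpec(seed=0)))

    def test_single_obs_closed_form(self):
        d = self._design_1obs(y=0.3)
        draws = self._draws_const(d, beta0=0.1, tau2=1.0)
        dev = log_density_per_obs(draws, d)
        expected = -2.0 * (-0.5 * np.log(2 * np.pi) - 0.5 * (0.3 - 0.1) ** 2)
        np.testing.assert_allclose(dev["deviance_draws"], expected, atol=1e-12)
        assert dev["deviance_at_mean"] == pytest.approx(expected, abs=1e-12)

    def test_duplicated_data_doubles_deviance(self):
        d1 = self._design_1obs(y=0.3)
        d2 = Design(
            y=np.array([0.3, 0.3]), X=np.array([[1.0], [1.0]]),
            col_names=["intercept"], prior_sd=np.array([10.0]),
            country_idx=np.array([0, 0]), countries=["C1"],
            region_of_country=np.array([0]), regions=["R1"],
            variant="national", stratum_reference="national",
            year_center=2015.0, year_scale=10.0, covariate_stats={},
            obs_stratum=np.array(["national"] * 2),
            obs_year=np.array([2010.0] * 2),
            obs_cci=np.full(2, inv_logit(0.3)))
        a = log_density_per_obs(self._draws_const(d1, 0.1, 1.0), d1)
        b = log_density_per_obs(self._draws_const(d2, 0.1, 1.0), d2)
        np.testing.assert_allclose(b["deviance_draws"],
                                   2 * a["deviance_draws"], atol=1e-12)

    def test_pd_nonnegative_on_fitted_model(self, small_fit):
        dev = log_density_per_obs(small_fit, small_fit.design)
        pD = dev["deviance_draws"].mean() - dev["deviance_at_mean"]
        assert pD > 0
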