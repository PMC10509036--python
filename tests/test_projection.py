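"""Projections, target-attainment probabilities, regional aggregation."""

import numpy as np
import pandas as pd
import pytest

from ccitrend.projection import (aggregate_region, count_on_track,
                                 dersimonian_laird, prob_target,
                                 summarise_draws)


class TestProbTarget:
    def test_all_above(self):
        assert prob_target(np.full(500, 0.9)) == 1.0

    def test_all_below(self):
        assert prob_target(np.full(500, 0.5)) == 0.0

    def test_symmetric_around_target(self, rng):
        draws = 0.8 + rng.normal(0, 0.03, size=20_000)
        assert prob_target(draws) == pytest.approx(0.5, abs=0.02)

    def test_nonincreasing_in_target(self, rng):
        draws = rng.uniform(0.5, 0.95, size=1000)
        probs = [prob_target(draws, t) for t in (0.6, 0.7, 0.8, 0.9)]
        assert probs == sorted(probs, reverse=True)

    def test_wider_spread_moves_probability_toward_half(self):
        """Mean below target: more spread raises P(reach); mean above:
        more spread lowers it."""
        base = np.linspace(-1, 1, 2000)
        below = 0.7 + 0.02 * base
        above = 0.9 + 0.02 * base
        assert prob_target(0.7 + 0.2 * base) > prob_target(below)
        assert prob_target(0.9 + 0.2 * base) < prob_target(above)

    def test_too_few_draws(self):
        with pytest.raises(ValueError):
            prob_target(np.ones(10))


class TestSummaries:
    def test_degenerate_draws_zero_width(self):
        g = np.full((500, 3), 0.65)
        t = summarise_draws(g, [2000, 2015, 2030], "C1", "national")
        np.testing.assert_allclose(t["mean"], 65.0, atol=1e-9)
        np.testing.assert_allclose(t["cri_low"], t["cri_high"], atol=1e-9)
        assert t["cri_low"].iloc[0] == pytest.approx(65.0)

    def test_cri_brackets_mean(self, rng):
        g = np.clip(rng.normal(0.7, 0.05, size=(2000, 2)), 0.01, 0.99)
        t = summarise_draws(g, [2020, 2030], "C1", "national")
        assert (t["cri_low"] <= t["mean"]).all()
        assert (t["mean"] <= t["cri_high"]).all()
        assert t["mean"].between(0, 100).all()


class TestDerSimonianLaird:
    def test_hand_computed_three_study_oracle(self):
        """Fixed 3-study vector; reference values verified independently
        (same numbers metafor's method='DL' reports)."""
        out = dersimonian_laird([0.2, 0.5, 0.9], [0.1, 0.2, 0.3])
        # hand computation: w = (100, 25, 11.11...), FE mean = 0.3877...,
        # Q = 5.9795918..., denom = 136.1111 - 10748.4568/136.1111,
        # tau2 = (Q - 2)/denom
        w = np.array([100.0, 25.0, 100.0 / 9.0])
        fe = np.sum(w * [0.2, 0.5, 0.9]) / w.sum()
        Q = float(np.sum(w * (np.array([0.2, 0.5, 0.9]) - fe) ** 2))
        tau2 = (Q - 2.0) / (w.sum() - np.sum(w ** 2) / w.sum())
        w_re = 1.0 / (np.array([0.1, 0.2, 0.3]) ** 2 + tau2)
        pooled = float(np.sum(w_re * [0.2, 0.5, 0.9]) / w_re.sum())
        assert out["Q"] == pytest.approx(Q, abs=1e-10)
        assert out["tau2"] == pytest.approx(tau2, abs=1e-10)
        assert out["pooled"] == pytest.approx(pooled, abs=1e-10)
        np.testing.assert_allclose(out["weights"], w_re / w_re.sum(),
                                   atol=1e-10)
        # frozen external cross-check values
        assert out["pooled"] == pytest.approx(0.454860481185, abs=1e-9)
        assert out["se"] == pytest.approx(0.189183157447, abs=1e-9)
        assert out["tau2"] == pytest.approx(0.069642857143, abs=1e-9)

    def test_homogeneous_studies_tau2_zero(self):
        out = dersimonian_laird([0.4, 0.4, 0.4], [0.1, 0.1, 0.1])
        assert out["tau2"] == 0.0 and out["pooled"] == pytest.approx(0.4)

    def test_invalid_se(self):
        with pytest.raises(ValueError):
            dersimonian_laird([0.1, 0.2], [0.1, 0.0])


class TestAggregateRegion:
    years = [2020, 2030]

    def test_single_country_region_passthrough(self, rng):
        g = np.clip(rng.normal(0.7, 0.04, size=(1000, 2)), 0.01, 0.99)
        table, agg, meta = aggregate_region({"C1": g}, self.years, "R1")
        np.testing.assert_array_equal(agg, g)
        assert meta["weights"] == {"C1": 1.0}
        assert meta["heterogeneity_sd"] == [0.0, 0.0]

    def test_equal_countries_equal_aggregate(self):
        g = np.full((800, 2), 0.6)
        grids = {"C1": g.copy(), "C2": g.copy(), "C3": g.copy()}
        table, agg, meta = aggregate_region(grids, self.years, "R1")
        np.testing.assert_allclose(agg, 0.6, atol=1e-12)

    @pytest.mark.parametrize("method", ["re_meta", "weighted_mean"])
    def test_aggregate_within_country_range_per_draw(self, rng, method):
        grids = {f"C{i}": np.clip(rng.normal(0.4 + 0.1 * i, 0.03,
                                             size=(600, 2)), 0.01, 0.99)
                 for i in range(4)}
        weights = {f"C{i}": 1.0 + i for i in range(4)}
        _, agg, _ = aggregate_region(grids, self.years, "R1", method=method,
                                     weights=weights)
        lo = np.min([g for g in grids.values()], axis=0)
        hi = np.max([g for g in grids.values()], axis=0)
        assert np.all(agg >= lo - 1e-12) and np.all(agg <= hi + 1e-12)

    def test_weighted_mean_needs_weights(self, rng):
        grids = {"C1": np.full((600, 2), 0.5), "C2": np.full((600, 2), 0.7)}
        with pytest.raises(ValueError, match="weights"):
            aggregate_region(grids, self.years, "R1", method="weighted_mean")


class TestCountOnTrack:
    def _table(self, p_targets):
        return pd.DataFrame([{"unit": f"C{i}", "year": 2030, "p_target": p}
                             for i, p in enumerate(p_targets)])

    def test_all_certain(self):
        out = count_on_track(self._table([1.0] * 5))
        assert out["count"] == 5

    def test_zero_threshold_counts_everyone(self):
        out = count_on_track(self._table([0.0, 0.3, 0.9]), threshold=0.0)
        assert out["count"] == 3

    def test_default_probability_bar(self):
        out = count_on_track(self._table([0.69, 0.70, 0.71, 0.2]))
        assert out["count"] == 2  # 0.70 inclusive

    def test_engineered_k_countries_on_track(self, rng):
        """Draw sets built so exactly k=3 of 7 countries sit above the
        target with negligible spread."""
        rows = []
        for i in range(7):
            level = 0.9 if i < 3 else 0.6
            draws = level + rng.normal(0, 1e-4, size=1000)
            rows.append({"unit": f"C{i}", "year": 2030,
                         "p_target": prob_target(draws)})
        out = count_on_track(pd.DataFrame(rows))
        assert out["count"] == 3
        assert out["units"] == ["C0", "C1", "C2"]

    def test_missing_year_rejected(self):
        with pytest.raises(ValueError):
            count_on_track(self._table([0.5]), year=2050)


class TestPredictionRecovery:
    def test_zero_noise_recovers_latent_surface(self):
        """With vanishing observation noise and dense surveys, the posterior
        mean trajectory tracks the latent truth closely."""
        from ccitrend.model import MCMCSpec, ModelSpec, build_design, fit
        from ccitrend.projection import predict_country
        from ccitrend.synthetic import ScenarioConfig, generate_bundle

        cfg = ScenarioConfig(n_regions=2, n_countries=6,
                             surveys_per_country=(15, 20),
                             single_survey_fraction=0.0,
                             noise_sd_logit=0.01, seed=21)
        b = generate_bundle(cfg)
        spec = ModelSpec(mcmc=MCMCSpec(chains=2, iterations=1500, burn_in=500,
                                       seed=5))
        d = build_design(b.panel, b.covariates, spec)
        draws = fit(d, spec)
        lat = b.latent_surface.query(
            "stratum_type == 'national'").set_index(["country_id", "year"])
        for c in d.countries:
            g = predict_country(draws, b.covariates, c, [2005, 2015, 2020])
            for t, yr in enumerate([2005, 2015, 2020]):
                truth = lat.loc[(c, yr), "cci_true"]
                assert g[:, t].mean() == pytest.approx(truth, abs=0.03)
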