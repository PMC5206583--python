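"""Monte Carlo projection engine and Red List categorization."""

import numpy as np
import pytest

from icepipe.ice_metrics import IceTrend
from icepipe.projection_engine import (ProjectionSummary, Scenario,
                                       aggregate_mgps, red_list_category,
                                       run_scenario, simulate_coefficients,
                                       summarize_changes, summarize_scenarios,
                                       three_generation_horizon)
from icepipe.relation_models import RelationFit


def trend(sub="R", slope=-1.26, slope_se=0.0, ice_2015=180.0, rsd=0.0):
    return IceTrend(sub, slope, ice_2015 - slope * 2015, slope_se, 0.0, rsd,
                    -1996.5 * slope_se ** 2, mean_year=1996.5,
                    mean_ice=ice_2015 - slope * 18.5, n_years=36)


def fit(beta, se=0.0, scope="global", approach=2):
    return RelationFit(approach, scope, beta, se, n_obs=10)


@pytest.mark.parametrize("gl, expected", [(11.5, 35), (13.6, 41), (12.0, 36)])
def test_three_generation_horizon_rounds_half_up(gl, expected):
    assert three_generation_horizon(gl) == expected


class TestSimulateCoefficients:
    def test_zero_se_degenerate(self):
        draws = simulate_coefficients(fit(0.013, 0.0), 100, seed=0)
        np.testing.assert_array_equal(draws, 0.013)

    def test_determinism(self):
        a = simulate_coefficients(fit(0.013, 0.002), 1000, seed=5)
        b = simulate_coefficients(fit(0.013, 0.002), 1000, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_mean_within_clt_bound(self):
        n = 62_500
        draws = simulate_coefficients(fit(0.013, 0.002), n, seed=1)
        assert abs(draws.mean() - 0.013) < 4 * 0.002 / np.sqrt(n)

    def test_trend_draws_reproduce_covariance(self):
        t = trend(slope_se=0.2, rsd=10.0)
        slope, intercept = simulate_coefficients(t, 200_000, seed=2)
        cov = np.cov(slope, intercept)[0, 1]
        assert cov == pytest.approx(-t.mean_year * 0.2 ** 2, rel=0.05)
        level = intercept + slope * t.mean_year
        assert level.std() == pytest.approx(10.0 / 6.0, rel=0.05)

    def test_missing_se_rejected(self):
        with pytest.raises(TypeError):
            simulate_coefficients(3.14, 10, seed=0)


class TestProjectSubpopulation:
    def scen(self, approach, gl=11.5):
        return Scenario(approach=approach, gl=gl, n_sims=10, seed=0)

    def test_zero_beta_zero_change(self):
        from icepipe.projection_engine import project_subpopulation
        c = project_subpopulation(self.scen(2), beta_draws=np.zeros(5),
                                  trend_draws=(np.full(5, -1.26), np.zeros(5)))
        np.testing.assert_array_equal(c, 0.0)

    def test_compounding_matches_annual_recursion(self):
        from icepipe.projection_engine import project_subpopulation
        c = project_subpopulation(self.scen(3), beta_draws=np.array([0.013]),
                                  trend_draws=(np.array([-1.26]), np.array([0.0])))
        # oracle: iterate 35 annual multiplicative steps
        n = 1.0
        for _ in range(35):
            n *= np.exp(0.013 * -1.26)
        assert c[0] == pytest.approx(n - 1.0, rel=1e-12)
        assert c[0] == pytest.approx(-0.436, abs=5e-4)

    def test_extreme_draw_floored(self):
        from icepipe.projection_engine import project_subpopulation
        c = project_subpopulation(self.scen(2), beta_draws=np.array([5.0]),
                                  trend_draws=(np.array([-3.0]), np.array([0.0])))
        assert c[0] == -1.0


class TestAggregate:
    def test_equal_changes_any_weights(self):
        out = aggregate_mgps({"A": -0.2, "B": -0.2}, {"A": 123.0, "B": 9.0})
        np.testing.assert_allclose(out, -20.0)

    def test_hand_weighted_mean(self):
        out = aggregate_mgps({"A": -0.10, "B": -0.50}, {"A": 1000.0, "B": 3000.0})
        np.testing.assert_allclose(out, -40.0)

    def test_single_subpopulation(self):
        np.testing.assert_allclose(aggregate_mgps({"A": -0.30}, {"A": 2500.0}), -30.0)

    def test_mismatched_sets_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            aggregate_mgps({"A": -0.1}, {"A": 1.0, "B": 2.0})


class TestSummaries:
    def test_threshold_probabilities_by_exhaustive_count(self):
        s = summarize_changes(Scenario(1, 11.5, n_sims=4),
                              np.array([-10.0, -35.0, -55.0, -90.0]))
        assert (s.p_decline_0, s.p_decline_30, s.p_decline_50, s.p_decline_80) \
            == (1.0, 0.75, 0.5, 0.25)

    def test_monotone_thresholds_on_random_runs(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            s = summarize_changes(Scenario(1, 11.5, n_sims=200),
                                  rng.normal(-40, 30, 200))
            probs = [s.p_decline_0, s.p_decline_30, s.p_decline_50, s.p_decline_80]
            assert all(np.diff(probs) <= 0)


class TestRunScenario:
    def world(self, beta=0.013, beta_se=0.0, slope_se=0.0, rsd=0.0):
        trends = {"A": trend("A", -1.26, slope_se, 150.0, rsd),
                  "B": trend("B", -2.0, slope_se, 200.0, rsd)}
        weights = {"A": 1000.0, "B": 3000.0}
        fits = {"global": fit(beta, beta_se),
                "seasonal": fit(beta, beta_se, "seasonal", 3)}
        ecos = {"A": "seasonal", "B": "seasonal"}
        return trends, weights, fits, ecos

    def test_degenerate_all_se_zero_beta_zero(self):
        trends, weights, fits, ecos = self.world(beta=0.0)
        s = run_scenario(Scenario(2, 11.5, n_sims=500, seed=0), trends, weights,
                         fits=fits)
        assert s.median_change == pytest.approx(0.0, abs=1e-12)
        assert s.p_decline_30 == 0.0

    def test_se_to_zero_matches_deterministic_point(self):
        trends, weights, fits, ecos = self.world()
        s = run_scenario(Scenario(3, 11.5, n_sims=300, seed=1), trends, weights,
                         fits=fits, ecoregions=ecos)
        expected = 100.0 * (
            1000.0 * (np.exp(0.013 * -1.26 * 35) - 1)
            + 3000.0 * (np.exp(0.013 * -2.0 * 35) - 1)
        ) / 4000.0
        assert s.median_change == pytest.approx(expected, abs=1e-10)
        assert s.ci_low == pytest.approx(expected, abs=1e-10)

    def test_end_to_end_recovery_within_mc_error(self):
        trends, weights, fits, ecos = self.world(beta_se=0.002, slope_se=0.1,
                                                 rsd=8.0)
        s = run_scenario(Scenario(3, 11.5, n_sims=40_000, seed=3), trends,
                         weights, fits=fits, ecoregions=ecos)
        analytic = 100.0 * (
            1000.0 * (np.exp(0.013 * -1.26 * 35) - 1)
            + 3000.0 * (np.exp(0.013 * -2.0 * 35) - 1)
        ) / 4000.0
        assert s.median_change == pytest.approx(analytic, abs=1.5)

    def test_doubling_sims_stays_within_binomial_error(self):
        trends, weights, fits, ecos = self.world(beta_se=0.004, slope_se=0.15)
        p = []
        for n in (20_000, 40_000):
            s = run_scenario(Scenario(3, 11.5, n_sims=n, seed=9), trends,
                             weights, fits=fits, ecoregions=ecos)
            p.append(s.p_decline_50)
        tol = 3 * np.sqrt(p[0] * (1 - p[0]) / 20_000) + 1e-3
        assert abs(p[1] - p[0]) < tol

    def test_missing_fit_rejected(self):
        trends, weights, _, ecos = self.world()
        with pytest.raises(ValueError, match="global"):
            run_scenario(Scenario(2, 11.5, n_sims=10), trends, weights)


class TestCrossScenario:
    def summaries(self):
        rows = [
            (1, 11.5, -30, -35, -25, 1.00, 0.56, 0.00, 0.00),
            (1, 13.6, -34, -40, -29, 1.00, 0.95, 0.00, 0.00),
            (2, 11.5, -4, -62, 50, 0.55, 0.20, 0.06, 0.00),
            (2, 13.6, -4, -68, 56, 0.55, 0.24, 0.08, 0.00),
            (3, 11.5, -43, -76, -20, 1.00, 0.86, 0.30, 0.01),
            (3, 13.6, -45, -79, -21, 1.00, 0.88, 0.35, 0.02),
        ]
        return [ProjectionSummary(Scenario(a, g, n_sims=1000), *rest)
                for a, g, *rest in rows]

    def test_published_medians(self):
        cross = summarize_scenarios(self.summaries())
        assert cross["thresholds"][30.0]["median"] == pytest.approx(0.71)
        assert cross["thresholds"][50.0]["median"] == pytest.approx(0.07)
        assert cross["thresholds"][80.0]["median"] <= 0.01

    def test_single_scenario_is_its_own_range(self):
        cross = summarize_scenarios(self.summaries()[:1])
        t30 = cross["thresholds"][30.0]
        assert t30["median"] == t30["min"] == t30["max"] == 0.56

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_scenarios([])


class TestRedList:
    def test_published_profile_is_vulnerable(self):
        r = red_list_category({0: 1.0, 30: 0.71, 50: 0.07, 80: 0.005})
        assert r.category == "vulnerable"

    def test_all_zero_not_threatened(self):
        r = red_list_category({0: 0.0, 30: 0.0, 50: 0.0, 80: 0.0})
        assert r.category == "least-concern-range"

    def test_high_p80_is_critically_endangered(self):
        r = red_list_category({0: 1.0, 30: 0.9, 50: 0.8, 80: 0.60})
        assert r.category == "critically-endangered"

    def test_non_monotone_rejected(self):
        with pytest.raises(ValueError, match="non-increasing"):
            red_list_category({0: 0.2, 30: 0.5, 50: 0.1, 80: 0.0})
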