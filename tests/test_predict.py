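"""Dynamic prediction and microsimulation forecasting."""

import numpy as np
import pytest

from spmaging.data import Individual
from spmaging.mixture import LatentClassModel
from spmaging.params import ConfigurationError, SPMParameters
from spmaging.predict import (Modification, ScenarioSpec, apply_scenario,
                              forecast_population, predict_individual,
                              predict_latent)
from spmaging.simulate import _simulate_paths


def _ind(obs_ages, obs_values, tau=None, delta=0, **kw):
    obs_ages = np.asarray(obs_ages, dtype=float)
    return Individual(0, obs_ages[0], obs_ages[-1] if tau is None else tau,
                      delta, obs_ages, np.asarray(obs_values, dtype=float),
                      **kw)


class TestPredictIndividual:
    def test_memoryless_exponential_case(self):
        # Q=0, constant mu0: S(u|s) = exp(-c (u - s)) whatever the history
        c = 0.04
        p = SPMParameters(a0=-0.2, b=1.0, Q0=0.0, mu0_c0=np.log(c),
                          mu0_theta=0.0)
        for vals in ([[0.0], [5.0]], [[8.0], [-3.0]]):
            pr = predict_individual(p, _ind([50.0, 54.0], vals), horizon=74.0)
            assert pr.survival[0] == pytest.approx(1.0)
            assert pr.survival[-1] == pytest.approx(np.exp(-c * 20.0),
                                                    rel=1e-8)

    def test_deviant_individual_has_lower_survival(self, params):
        on_norm = 80.0 + 0.2 * 50.0         # f0 at age 50
        norm_ind = _ind([40.0, 50.0], [[on_norm], [on_norm]])
        deviant = _ind([40.0, 50.0], [[on_norm], [on_norm + 15.0]])
        pn = predict_individual(params, norm_ind, horizon=80.0)
        pd_ = predict_individual(params, deviant, horizon=80.0)
        assert np.all(pd_.survival <= pn.survival + 1e-12)
        assert pd_.survival[-1] < pn.survival[-1]

    def test_monte_carlo_oracle(self, params):
        # conditional survival from (s, y_s) matches restarted simulation
        s, ys = 50.0, 95.0
        ind = _ind([40.0, s], [[90.0], [ys]])
        grid = np.array([s, 55.0, 60.0, 65.0, 70.0, 75.0])
        pr = predict_individual(params, ind, grid=grid)
        n = 100_000
        rng = np.random.default_rng(19)
        _, _, tau, delta = _simulate_paths(params, n, s, 75.0, 0.05, rng,
                                           y0=np.full((n, 1), ys))
        for a, S in zip(grid[1:], pr.survival[1:]):
            Smc = ((tau > a) | ((tau >= a) & (delta == 0))).mean()
            se = np.sqrt(max(Smc * (1 - Smc), 1e-12) / n)
            assert abs(S - Smc) < 3 * se + 2e-3   # + O(dt) event placement

    def test_tower_property(self, params):
        ind = _ind([40.0, 46.0], [[90.0], [93.0]])
        u = 80.0
        direct = predict_individual(params, ind, grid=np.array([46.0, 60.0, u]))
        S_u = direct.survival[-1]
        S_mid = direct.survival[1]
        # predict 46 -> 60, then continue with the propagated state 60 -> 80
        two_leg = predict_individual(params, ind, s=60.0,
                                     grid=np.array([60.0, u]))
        # two_leg conditions on survival to 60: S(80|46) = S(60|46)*S(80|60)
        assert S_mid * two_leg.survival[-1] == pytest.approx(S_u, rel=1e-6)

    def test_update_with_new_observation_changes_forecast(self, params):
        hist1 = _ind([40.0, 50.0], [[90.0], [92.0]])
        hist2 = _ind([40.0, 50.0, 56.0], [[90.0], [92.0], [105.0]])
        p1 = predict_individual(params, hist1, horizon=85.0)
        p2 = predict_individual(params, hist2, horizon=85.0)
        assert p2.s > p1.s
        assert p2.survival[-1] != pytest.approx(p1.survival[-1], rel=1e-3)

    def test_needs_observation_before_s(self, params):
        ind = _ind([50.0], [[90.0]])
        with pytest.raises(Exception, match="before|observation"):
            predict_individual(params, ind, s=45.0, horizon=80.0)


class TestPredictionPlot:
    def test_plot_returns_axis(self, params):
        import matplotlib
        matplotlib.use("Agg")
        pr = predict_individual(params, _ind([40.0, 50.0], [[90.0], [92.0]]),
                                horizon=80.0)
        ax = pr.plot()
        assert ax.get_xlabel() == "age (years)"


class TestPredictLatent:
    def test_K1_equals_basic(self, params):
        m = LatentClassModel([params])
        ind = _ind([40.0, 48.0], [[90.0], [94.0]])
        a = predict_latent(m, ind, horizon=80.0)
        b = predict_individual(params, ind, horizon=80.0)
        assert np.allclose(a.survival, b.survival, rtol=1e-10)

    def test_observed_genotype_uses_that_regime(self, params):
        c2 = params.copy(); c2.Q0 = params.Q0 * 5
        m = LatentClassModel([params, c2], beta0=[0.0])
        ind = _ind([40.0, 48.0], [[90.0], [94.0]], genotype=2)
        a = predict_latent(m, ind, horizon=80.0)
        b = predict_individual(c2, ind, horizon=80.0)
        assert np.allclose(a.survival, b.survival, rtol=1e-10)

    def test_mixture_is_posterior_weighted_average(self, params, monkeypatch):
        c2 = params.copy(); c2.Q0 = params.Q0 * 5
        m = LatentClassModel([params, c2], beta0=[0.0])
        ind = _ind([40.0, 48.0], [[90.0], [94.0]])
        import spmaging.predict as pp
        monkeypatch.setattr(pp, "posterior_class",
                            lambda model, i: np.array([0.9, 0.1]))
        mix = predict_latent(m, ind, horizon=80.0)
        s1 = predict_individual(params, ind, horizon=80.0).survival
        s2 = predict_individual(c2, ind, horizon=80.0).survival
        assert np.allclose(mix.survival, 0.9 * s1 + 0.1 * s2, rtol=1e-10)


class TestScenarios:
    def test_invalid_scenario_rejected(self, params):
        bad = ScenarioSpec("negQ", [Modification("Q", "scale", -1.0)])
        with pytest.raises(ConfigurationError, match="indefinite"):
            apply_scenario(params, bad)

    def test_unknown_component_rejected(self):
        with pytest.raises(ConfigurationError):
            Modification("R", "scale", 0.5)

    def test_modification_applies_from_start_age(self, params):
        sc = ScenarioSpec("lateQ", [Modification("Q", "scale", 0.0)],
                          start_age=60.0)
        mod = apply_scenario(params, sc)
        c = mod.components(np.array([50.0, 70.0]))
        assert c["Q"][0, 0, 0] > 0
        assert c["Q"][1, 0, 0] == 0.0


class TestForecastPopulation:
    def test_null_scenario_paired_identity(self, params):
        tab = forecast_population(params, 40.0, 90.0, n_sim=3000,
                                  scenario=ScenarioSpec("null", []), seed=2)
        assert np.array_equal(tab["survival_base"], tab["survival_null"])
        assert np.array_equal(tab["mean_y_base"], tab["mean_y_null"])

    def test_reproducible_given_seed(self, params):
        a = forecast_population(params, 40.0, 90.0, n_sim=2000, seed=3)
        b = forecast_population(params, 40.0, 90.0, n_sim=2000, seed=3)
        assert a.equals(b)

    def test_scaling_Q_down_never_hurts_survival(self, params):
        sc = ScenarioSpec("resist", [Modification("Q", "scale", 0.3)])
        tab = forecast_population(params, 40.0, 95.0, n_sim=5000,
                                  scenario=sc, seed=4)
        assert np.all(tab["survival_resist"] >= tab["survival_base"] - 1e-12)

    def test_q_zero_matches_gompertz_closed_form(self, params):
        sc = ScenarioSpec("noQ", [Modification("Q", "scale", 0.0)])
        tab = forecast_population(params, 40.0, 95.0, n_sim=50_000,
                                  scenario=sc, seed=5)
        th, c0 = params.mu0_theta, params.mu0_c0
        ages = tab["age"].to_numpy()
        exact = np.exp(-(np.exp(c0) / th) * (np.exp(th * ages)
                                             - np.exp(th * 40.0)))
        z = (tab["survival_noQ"] - exact) / np.maximum(
            tab["survival_se_noQ"], 1e-12)
        assert np.max(np.abs(z.to_numpy())) < 3.5

    def test_halving_mu0_doubles_median_remaining_lifetime(self):
        # exponential case: median = ln 2 / c
        c = 0.05
        p = SPMParameters(a0=-0.2, b=1.0, Q0=0.0, mu0_c0=np.log(c),
                          mu0_theta=0.0, m0=0.0, gamma0=1.0,
                          age_range=(0.0, 500.0))
        sc = ScenarioSpec("half", [Modification("mu0", "scale", 0.5)])
        tab = forecast_population(p, 0.0, 400.0, n_sim=40_000, scenario=sc,
                                  seed=6, grid=np.array([0.0, 400.0]))
        med = tab.attrs["median_lifetime"]
        ratio = med["half"] / med["base"]
        assert ratio == pytest.approx(2.0, rel=0.06)
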