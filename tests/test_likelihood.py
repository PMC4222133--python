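"""Moment ODEs, conditional hazard, likelihood factorisation, survival."""

import numpy as np
import pytest

from spmaging.data import Cohort, Individual
from spmaging.likelihood import (MomentState, cohort_loglik,
                                 conditional_hazard, discrete_time_loglik,
                                 individual_loglik, individual_logliks,
                                 marginal_survival, moment_derivatives,
                                 prepare_cohort)
from spmaging.params import SPMParameters
from spmaging.presets import study_params
from spmaging.simulate import mc_survival, simulate_cohort


def _ind(obs_ages, obs_values, t0=None, tau=None, delta=0, **kw):
    obs_ages = np.asarray(obs_ages, dtype=float)
    return Individual(0, obs_ages[0] if t0 is None else t0,
                      obs_ages[-1] if tau is None else tau, delta,
                      obs_ages, np.asarray(obs_values, dtype=float), **kw)


class TestMomentDerivatives:
    def test_drift_arithmetic(self):
        p = SPMParameters(a0=-0.1, f1_0=100.0, Q0=0.0, b=1.0)
        dm, _ = moment_derivatives(p, None, MomentState(50.0, [110.0], [[3.0]]))
        assert dm[0] == pytest.approx(-1.0)

    def test_variance_closed_form(self):
        # Q=0: gamma(t) = B^2 (1 - e^{2 a dt}) / (-2a); a=-0.1, B=2, dt=10
        p = SPMParameters(a0=-0.1, f1_0=0.0, b=2.0, Q0=0.0)
        from spmaging.likelihood import _adaptive_segment
        _, G, _, _ = _adaptive_segment(p, None, 0.0, 10.0,
                                       np.zeros(1), np.zeros((1, 1)))
        exact = 4 * (1 - np.exp(-2.0)) / 0.2
        assert G[0, 0] == pytest.approx(17.2933, abs=2e-4)
        assert abs(G[0, 0] - exact) / exact < 1e-6

    def test_stationary_point(self):
        p = SPMParameters(a0=-0.2, f1_0=80.0, b=2.0, Q0=0.0)
        g_stat = 4.0 / 0.4
        dm, dG = moment_derivatives(p, None,
                                    MomentState(50.0, [80.0], [[g_stat]]))
        assert dm[0] == pytest.approx(0.0)
        assert dG[0, 0] == pytest.approx(0.0)


class TestConditionalHazard:
    def test_minimum_at_norm(self):
        p = SPMParameters(f0_0=70.0, Q0=1e-3, mu0_c0=np.log(0.01),
                          mu0_theta=0.0)
        mu = conditional_hazard(p, None, MomentState(50.0, [70.0], [[0.0]]))
        assert mu == pytest.approx(0.01)

    def test_quadratic_term(self):
        p = SPMParameters(f0_0=0.0, Q0=1e-3, mu0_c0=np.log(0.01),
                          mu0_theta=0.0)
        mu = conditional_hazard(p, None, MomentState(50.0, [10.0], [[0.0]]))
        assert mu == pytest.approx(0.11)

    def test_trace_term(self):
        p = SPMParameters(f0_0=0.0, Q0=1e-3, mu0_c0=np.log(0.01),
                          mu0_theta=0.0)
        mu = conditional_hazard(p, None, MomentState(50.0, [10.0], [[5.0]]))
        assert mu == pytest.approx(0.115)


class TestIndividualLoglik:
    def test_exponential_survival_only(self):
        # single baseline observation, censored: contribution = -c (tau - t0)
        c = 0.03
        p = SPMParameters(a0=-0.1, b=1.0, Q0=0.0, mu0_c0=np.log(c),
                          mu0_theta=0.0)
        ind = _ind([50.0], [[0.0]], tau=70.0, delta=0)
        ll = individual_loglik(p, ind)
        assert ll == pytest.approx(-c * 20.0, rel=1e-8)

    def test_gaussian_transition_density(self):
        # a=0, B=1, Q=0, mu0=0; y(0)=5, y(4)=5 -> log N(5; 5, 4)
        p = SPMParameters(a0=0.0, b=1.0, Q0=0.0, mu0_c0=-np.inf)
        ind = _ind([0.0, 4.0], [[5.0], [5.0]])
        exact = -0.5 * np.log(2 * np.pi * 4.0)
        assert individual_loglik(p, ind) == pytest.approx(exact, abs=1e-6)
        assert round(exact, 4) == -1.6121

    def test_gompertz_survival_closed_form(self):
        # Q=0 with Gompertz mu0: -int mu0 = -(e^c0/theta)(e^{th t} - e^{th t0})
        c0, th = np.log(1e-3) - 0.085 * 40, 0.085
        p = SPMParameters(a0=-0.3, b=2.0, Q0=0.0, mu0_c0=c0, mu0_theta=th)
        ind = _ind([40.0], [[0.0]], tau=75.0, delta=0)
        exact = -(np.exp(c0) / th) * (np.exp(th * 75) - np.exp(th * 40))
        assert individual_loglik(p, ind) == pytest.approx(exact, rel=1e-8)
        assert individual_loglik(p, ind, solver="adaptive") == \
            pytest.approx(exact, rel=1e-8)

    def test_event_term_adds_log_hazard(self):
        c = 0.05
        p = SPMParameters(a0=-0.1, b=1.0, Q0=0.0, mu0_c0=np.log(c),
                          mu0_theta=0.0)
        cens = _ind([50.0], [[0.0]], tau=60.0, delta=0)
        died = _ind([50.0], [[0.0]], tau=60.0, delta=1)
        assert individual_loglik(p, died) - individual_loglik(p, cens) == \
            pytest.approx(np.log(c), rel=1e-8)

    def test_measurement_error_filter_matches_exact_in_limit(self, params):
        ind = _ind([40.0, 44.0, 48.0], [[90.0], [92.0], [88.0]],
                   tau=52.0, delta=0)
        exact = individual_loglik(params, ind, solver="adaptive")
        filt = individual_loglik(params, ind, measurement_sd=1e-6)
        assert filt == pytest.approx(exact, rel=1e-5)

    def test_filter_update_shrinks_toward_observation(self, params):
        # with noise the filtered likelihood differs and stays finite
        ind = _ind([40.0, 44.0, 48.0], [[90.0], [92.0], [88.0]],
                   tau=52.0, delta=0)
        ll = individual_loglik(params, ind, measurement_sd=2.0)
        assert np.isfinite(ll)
        assert ll != pytest.approx(individual_loglik(params, ind))


class TestCohortLoglik:
    def test_singleton_equals_individual(self, params, cohort):
        ind = cohort.individuals[3]
        single = Cohort([ind])
        assert cohort_loglik(params, single) == pytest.approx(
            individual_loglik(params, ind), rel=1e-12)

    def test_duplication_doubles(self, params, cohort):
        sub = Cohort(cohort.individuals[:20])
        dup = Cohort([Individual(i, d.t0, d.tau, d.delta, d.obs_ages,
                                 d.obs_values, d.x, d.genotype)
                      for i, d in enumerate(sub.individuals * 2)])
        assert cohort_loglik(params, dup) == pytest.approx(
            2 * cohort_loglik(params, sub), rel=1e-12)

    def test_permutation_invariance(self, params, cohort):
        sub = Cohort(cohort.individuals[:50])
        perm = Cohort(list(reversed(sub.individuals)))
        a, b = cohort_loglik(params, sub), cohort_loglik(params, perm)
        assert abs(a - b) <= 1e-9 * abs(a)

    def test_vectorised_matches_adaptive_reference(self, params, cohort):
        sub = cohort.subset([i < 40 for i in range(len(cohort))])
        fast = individual_logliks(params, sub, h_target=0.05)
        ref = individual_logliks(params, sub, solver="adaptive")
        assert np.max(np.abs(fast - ref)) < 1e-6

    def test_truth_beats_perturbations(self, params, scheme):
        # likelihood sanity: generating truth beats +/-25% perturbations
        coh = simulate_cohort(params, 2000, scheme, rng=77)
        prep = prepare_cohort(coh, params)
        ll0 = cohort_loglik(params, coh, prep)
        rng = np.random.default_rng(5)
        fields = ["a0", "f1_0", "f1_1", "b", "Q0", "mu0_c0", "mu0_theta"]
        wins = 0
        for _ in range(20):
            q = params.copy()
            for f in rng.choice(fields, size=3, replace=False):
                v = getattr(q, f)
                setattr(q, f, v * (1 + rng.choice([-0.25, 0.25])))
            if cohort_loglik(q, coh, prep) < ll0:
                wins += 1
        assert wins >= 19


class TestMarginalSurvival:
    def test_exponential_case(self):
        p = SPMParameters(a0=-0.1, b=1.0, Q0=0.0, mu0_c0=np.log(0.05),
                          mu0_theta=0.0)
        _, S = marginal_survival(p, t0=40.0, horizon=60.0,
                                 grid=np.array([40.0, 60.0]))
        assert S[-1] == pytest.approx(np.exp(-1.0), rel=1e-8)

    def test_gompertz_closed_form(self):
        c0, th = -11.0, 0.09
        p = SPMParameters(a0=-0.2, b=2.0, Q0=0.0, mu0_c0=c0, mu0_theta=th)
        grid = np.linspace(40.0, 95.0, 12)
        _, S = marginal_survival(p, grid=grid)
        exact = np.exp(-(np.exp(c0) / th) * (np.exp(th * grid)
                                             - np.exp(th * grid[0])))
        assert np.max(np.abs(S - exact) / exact) < 1e-8

    def test_monotone_and_anchored(self, params):
        grid = np.linspace(40.0, 100.0, 61)
        _, S = marginal_survival(params, grid=grid)
        assert S[0] == pytest.approx(1.0)
        assert np.all(np.diff(S) <= 1e-12)

    def test_agrees_with_monte_carlo(self, params):
        grid = np.linspace(45.0, 95.0, 10)
        _, S = marginal_survival(params, t0=40.0, horizon=95.0, grid=grid)
        Smc, se = mc_survival(params, 50_000, 40.0, 95.0, grid, rng=4)
        z = (S - Smc) / np.maximum(se, 1e-12)
        assert np.max(np.abs(z)) < 3.5


class TestDiscreteTime:
    def test_single_transition_gaussian(self):
        p = SPMParameters(a0=0.0, b=1.0, Q0=0.0, mu0_c0=-np.inf)
        ind = _ind([0.0, 4.0], [[5.0], [5.0]])
        ll = discrete_time_loglik(p, Cohort([ind]), step=4.0)
        assert ll == pytest.approx(-0.5 * np.log(2 * np.pi * 4.0), abs=1e-12)

    def test_zero_hazard_survival_factors_vanish(self):
        # mu = 0 everywhere: only the Gaussian transition terms remain
        p = SPMParameters(a0=-0.1, f1_0=0.0, b=1.0, Q0=0.0, mu0_c0=-np.inf)
        ys = [0.1, 0.2, 0.0]
        ind = _ind([0.0, 1.0, 2.0], [[y] for y in ys], tau=2.5, delta=0)
        ll = discrete_time_loglik(p, Cohort([ind]), step=1.0)
        manual = sum(
            -0.5 * (np.log(2 * np.pi) + (y1 - (y0 - 0.1 * y0)) ** 2)
            for y0, y1 in zip(ys[:-1], ys[1:]))
        assert ll == pytest.approx(manual, abs=1e-12)
        # adding a constant hazard only subtracts survival mass
        pz = SPMParameters(a0=-0.1, f1_0=0.0, b=1.0, Q0=0.0,
                           mu0_c0=np.log(0.04), mu0_theta=0.0)
        assert discrete_time_loglik(pz, Cohort([ind]), step=1.0) < ll

    def test_off_grid_ages_raise_unless_binned(self):
        p = SPMParameters(a0=0.0, b=1.0, Q0=0.0, mu0_c0=-np.inf)
        ind = _ind([0.0, 1.37], [[0.0], [0.5]])
        with pytest.raises(Exception, match="grid"):
            discrete_time_loglik(p, Cohort([ind]), step=0.5)
        assert np.isfinite(discrete_time_loglik(p, Cohort([ind]), step=0.5,
                                                bin_ages=True))

    def test_converges_to_continuous_for_small_step(self, params):
        # dense exams: discrete and continuous likelihoods agree closely
        from spmaging.presets import study_scheme
        sch = study_scheme(spacing=0.05, n_exams=201, censor_age=55.0)
        coh = simulate_cohort(params, 500, sch, dt=0.05, rng=41)
        ll_d = discrete_time_loglik(params, coh, step=0.05, bin_ages=True)
        ll_c = cohort_loglik(params, coh, h_target=0.05)
        assert abs(ll_d - ll_c) / abs(ll_c) < 0.005


class TestGammaMonitoring:
    def test_gamma_stays_psd_under_integration(self, params, cohort):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("error")       # no PSD-clip warnings
            individual_logliks(params, Cohort(cohort.individuals[:50]))
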