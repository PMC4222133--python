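"""Simulator: SDE trajectories, event generation, schemes, mixtures."""

import numpy as np
import pytest
from scipy import stats

from spmaging.data import ObservationScheme
from spmaging.mixture import LatentClassModel
from spmaging.params import SPMParameters
from spmaging.presets import study_params, study_scheme
from spmaging.simulate import (mc_survival, sample_class, simulate_cohort,
                               simulate_path)


class TestSimulatePath:
    def test_drift_fixed_point_zero_hazard(self):
        # B=0, Q=0, mu0=0, y0=f1 constant: path stays at f1, censored
        p = SPMParameters(a0=-0.5, f1_0=50.0, b=0.0, Q0=0.0,
                          mu0_c0=-np.inf)
        ages, path, event_age, delta = simulate_path(
            p, t0=0.0, y0=[50.0], horizon=20.0, rng=np.random.default_rng(0))
        assert delta == 0 and event_age is None
        assert np.allclose(path, 50.0)

    def test_exponential_lifetime_mean(self):
        # Q=0, mu0=c constant: lifetime is exponential with mean 1/c
        c = 0.05
        p = SPMParameters(a0=-0.1, b=1.0, Q0=0.0, mu0_c0=np.log(c),
                          mu0_theta=0.0)
        from spmaging.simulate import _simulate_paths
        rng = np.random.default_rng(42)
        n = 100_000
        _, _, tau, delta = _simulate_paths(p, n, 0.0, 400.0, 0.05, rng,
                                           y0=np.zeros((n, 1)))
        assert delta.mean() > 0.999
        mean = tau[delta == 1].mean()
        se = (1 / c) / np.sqrt(n)
        assert abs(mean - 1 / c) < 3 * se + 0.025  # + O(dt) placement bias

    def test_ou_moments_closed_form(self):
        # a=-0.1, f1=100, B=2, zero hazard: OU mean/variance at t0+10
        p = SPMParameters(a0=-0.1, f1_0=100.0, b=2.0, Q0=0.0, mu0_c0=-np.inf)
        from spmaging.simulate import _simulate_paths
        rng = np.random.default_rng(3)
        n = 100_000
        _, rec, _, _ = _simulate_paths(p, n, 0.0, 10.0, 0.05, rng,
                                       y0=np.full((n, 1), 110.0),
                                       record_steps=[200])
        y10 = rec[0, :, 0]
        m_exact = 100 + 10 * np.exp(-1.0)          # 103.6788
        v_exact = 4 * (1 - np.exp(-2.0)) / 0.2     # 17.2933
        assert abs(y10.mean() - m_exact) < 3 * np.sqrt(v_exact / n) + 0.02
        se_v = v_exact * np.sqrt(2 / n)
        assert abs(y10.var() - v_exact) < 3 * se_v + 0.05

    def test_nonfinite_state_raises(self):
        p = SPMParameters(a0=5.0, f1_0=0.0, b=1.0, Q0=0.0, mu0_c0=-np.inf)
        with pytest.raises(Exception, match="age"):
            simulate_path(p, t0=0.0, y0=[100.0], horizon=200.0,
                          rng=np.random.default_rng(0))


class TestSampleClass:
    def test_zero_coefficients_symmetric(self, rng):
        label, prob = sample_class(np.array([0.0]), rng=rng)
        assert prob == pytest.approx([0.5, 0.5])

    def test_logit_arithmetic(self, rng):
        _, prob = sample_class(np.array([np.log(3.0)]), rng=rng)
        assert prob == pytest.approx([0.75, 0.25])

    def test_three_class_symmetry(self, rng):
        from spmaging.mixture import MixtureModel
        m = MixtureModel([SPMParameters() for _ in range(3)],
                         beta0=[0.0, 0.0], beta1=np.zeros((2, 1)),
                         membership_covariates=("x",))
        _, prob = sample_class(m, x0=[2.0], rng=rng)
        assert prob == pytest.approx([1 / 3] * 3)


class TestSimulateCohort:
    def test_genotyped_fraction_boundaries(self, params, scheme):
        mix = LatentClassModel([params, params], beta0=[0.0])
        full = simulate_cohort(mix, 50, scheme, genotyped_fraction=1.0, rng=0)
        none = simulate_cohort(mix, 50, scheme, genotyped_fraction=0.0, rng=0)
        assert all(i.genotype is not None for i in full)
        assert all(i.genotype is None for i in none)

    def test_symmetric_logit_class_share(self, params, scheme):
        mix = LatentClassModel([params, params], beta0=[0.0])
        coh = simulate_cohort(mix, 100_000, scheme, rng=11)
        share = (coh.true_classes == 1).mean()
        assert abs(share - 0.5) < 3 * 0.5 / np.sqrt(100_000)

    def test_identical_regimes_match_single_class(self, params, scheme):
        # mixture of identical components is distributionally a single SPM
        mix = LatentClassModel([params.copy(), params.copy()], beta0=[0.3])
        tau_mix = np.array([i.tau for i in
                            simulate_cohort(mix, 10_000, scheme, rng=21)])
        tau_one = np.array([i.tau for i in
                            simulate_cohort(params, 10_000, scheme, rng=22)])
        _, pval = stats.ks_2samp(tau_mix, tau_one)
        assert pval > 0.01

    def test_seed_determinism(self, params, scheme):
        a = simulate_cohort(params, 40, scheme, rng=5)
        b = simulate_cohort(params, 40, scheme, rng=5)
        for ia, ib in zip(a, b):
            assert ia.tau == ib.tau and ia.delta == ib.delta
            assert np.array_equal(ia.obs_ages, ib.obs_ages)
            assert np.array_equal(ia.obs_values, ib.obs_values)

    def test_observations_respect_terminal_age(self, cohort):
        for ind in cohort:
            assert ind.obs_ages.size >= 1
            assert ind.obs_ages[-1] <= ind.tau + 1e-12
            assert np.all(np.diff(ind.obs_ages) > 0)

    def test_missingness_and_jitter(self, params):
        sch = study_scheme(jitter_sd=0.2, miss_prob=0.3)
        coh = simulate_cohort(params, 300, sch, rng=9)
        n_obs = np.array([i.obs_ages.size for i in coh])
        assert n_obs.max() <= 16
        assert n_obs.mean() < 14      # thinning happened
        offgrid = [a for i in coh for a in i.obs_ages - 40.0
                   if abs(a / 2.0 - round(a / 2.0)) > 1e-9]
        assert offgrid                # jitter moved exams off the 2y grid

    def test_measurement_noise_increases_spread(self, params):
        base = simulate_cohort(params, 400, study_scheme(), rng=13)
        noisy = simulate_cohort(params, 400,
                                study_scheme(measurement_sd=5.0), rng=13)
        v0 = np.var(np.concatenate([i.obs_values[:, 0] for i in base]))
        v1 = np.var(np.concatenate([i.obs_values[:, 0] for i in noisy]))
        assert v1 > v0 + 10.0


class TestWeakConvergence:
    def test_euler_bias_below_monte_carlo_noise(self):
        # at both step sizes the 100k-path mean is within MC error of the
        # exact OU mean, i.e. halving dt changes nothing detectable
        p = study_params(f1_1=0.0, Q0=0.0, q1=0.0, mu0_c0=-np.inf)
        from spmaging.simulate import _simulate_paths
        n = 100_000
        exact = 80.0 + 15.0 * np.exp(-0.3 * 10)
        out = {}
        for dt in (0.1, 0.05):
            rng = np.random.default_rng(33)
            steps = [int(round(10 / dt))]
            _, rec, _, _ = _simulate_paths(p, n, 40.0, 50.0, dt, rng,
                                           y0=np.full((n, 1), 95.0),
                                           record_steps=steps)
            out[dt] = rec[0, :, 0]
        se = out[0.05].std() / np.sqrt(n)
        for dt in (0.1, 0.05):
            assert abs(out[dt].mean() - exact) < 3 * se
        assert abs(out[0.1].mean() - out[0.05].mean()) < 3 * np.sqrt(2) * se
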