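"""Cohort simulation: Euler--Maruyama trajectories of the biomarker SDE,
event times from the quadratic hazard, sparse examination schedules,
latent-class / genotype membership, and partial genotyping.

The simulator is both the package's synthetic-data generator and the
Monte-Carlo oracle against which the moment-ODE likelihood is checked.
Events are generated stepwise with probability 1 - exp(-mu(t_k, y_k) dt)
and the event age is reported at the step midpoint (O(dt) placement).
All randomness flows through one seeded generator in a fixed order, so a
given seed and configuration reproduce a cohort exactly.
"""

from __future__ import annotations

import numpy as np

from .data import Cohort, Individual, ObservationScheme, DataError
from .mixture import MixtureModel, class_probabilities, sample_class
from .params import SPMParameters, ConfigurationError

__all__ = ["simulate_path", "simulate_cohort", "mc_survival", "sample_class",
           "SimulationError"]


class SimulationError(RuntimeError):
    pass


def _draw_y0(model, n, rng):
    J = model.dim
    z = rng.standard_normal((n, J))
    g = model.gamma0
    L = np.linalg.cholesky(g + 1e-300 * np.eye(J)) if np.any(g) else np.zeros((J, J))
    return model.m0[None, :] + z @ L.T


def _simulate_paths(model, n, t0, horizon, dt, rng, X=None, y0=None,
                    keep_path=False, record_steps=None):
    """Vectorised Euler--Maruyama + stepwise event generation.

    Returns ``(grid, paths_or_None, tau, delta)``; ``paths`` has shape
    (n_steps+1, n, J) when ``keep_path``, or (len(record_steps), n, J) when
    only selected step indices are recorded.  The normal and uniform draws
    are consumed every step for every individual regardless of vital status,
    so two runs from the same seed are path-wise paired even under different
    hazard parameters (common random numbers)."""
    J = model.dim
    n_steps = int(np.ceil((horizon - t0) / dt - 1e-9))
    if n_steps < 1:
        raise ConfigurationError("horizon must exceed t0 by at least dt")
    grid = t0 + dt * np.arange(n_steps + 1)
    y = np.array(y0, dtype=float).reshape(n, J) if y0 is not None \
        else _draw_y0(model, n, rng)
    alive = np.ones(n, dtype=bool)
    tau = np.full(n, grid[-1])
    delta = np.zeros(n, dtype=np.int8)
    paths = np.empty((n_steps + 1, n, J)) if keep_path else None
    if keep_path:
        paths[0] = y
    rec = None
    rec_at: dict[int, int] = {}
    if record_steps is not None:
        record_steps = np.asarray(record_steps, dtype=int)
        rec = np.empty((record_steps.size, n, J))
        rec_at = {int(s): i for i, s in enumerate(record_steps)}
        if 0 in rec_at:
            rec[rec_at[0]] = y
    sq = np.sqrt(dt)
    for k in range(n_steps):
        t = np.full(n, grid[k])
        c = model.components(t, X)
        z = rng.standard_normal((n, J))
        u = rng.random(n)
        # event probability over the step uses the hazard at the midpoint
        # age (events are reported at the midpoint): cancels the leading
        # O(dt) bias for age-increasing hazards
        cm = model.components(t + dt / 2, X)
        dev = y - cm["f0"]
        mu = cm["mu0"] + np.einsum("mi,mij,mj->m", dev, cm["Q"], dev)
        dies = alive & (u < -np.expm1(-np.maximum(mu, 0.0) * dt))
        tau[dies] = grid[k] + dt / 2
        delta[dies] = 1
        alive &= ~dies
        drift = np.einsum("mij,mj->mi", c["a"], y - c["f1"])
        noise = np.einsum("mij,mj->mi", c["B"], z)
        y = y + drift * dt + noise * sq
        if not np.all(np.isfinite(y[alive])):
            raise SimulationError(
                f"non-finite state at age {grid[k + 1]:.2f} (diverging dynamics; "
                "check the feedback matrix a)")
        if keep_path:
            paths[k + 1] = y
        if rec is not None and (k + 1) in rec_at:
            rec[rec_at[k + 1]] = y
    return grid, (rec if rec is not None else paths), tau, delta


def simulate_path(params: SPMParameters, x=None, t0: float = 0.0, y0="draw",
                  dt: float = 0.05, horizon: float = 100.0, rng=None):
    """Simulate one biomarker trajectory and its event time.

    Returns ``(ages, path (n_steps+1, J), event_age_or_None, delta)``;
    ``event_age`` is None when the path is censored at the horizon.
    ``y0`` may be a J-vector or ``"draw"`` to sample the initial law."""
    rng = np.random.default_rng() if rng is None else rng
    if dt <= 0:
        raise ConfigurationError("dt must be > 0")
    p = len(params.covariates)
    X = None if p == 0 else np.asarray(x, dtype=float).reshape(1, p)
    y0v = None if isinstance(y0, str) and y0 == "draw" \
        else np.asarray(y0, dtype=float).reshape(1, params.dim)
    grid, paths, tau, delta = _simulate_paths(
        params, 1, t0, horizon, dt, rng, X=X, y0=y0v, keep_path=True)
    # truncate the stored path at the event step
    if delta[0]:
        keep = grid <= tau[0]
        return grid[keep], paths[keep, 0], float(tau[0]), 1
    return grid, paths[:, 0], None, 0


def simulate_cohort(model, n: int, scheme: ObservationScheme,
                    genotyped_fraction: float = 1.0, rng=None,
                    t0: float | None = None, dt: float = 0.05,
                    covariate_sampler=None, covariate_names=(),
                    seed_record: int | None = None) -> Cohort:
    """Generate a synthetic cohort under a basic SPM or a K-regime mixture.

    For a :class:`MixtureModel`, each individual's regime is drawn from the
    multinomial-logistic membership model given baseline covariates; the
    regime label is recorded as the genotype with probability
    ``genotyped_fraction`` (1 = everyone genotyped, 0 = fully latent).  The
    generating model and true labels are stored on the returned cohort.

    ``covariate_sampler(rng, n) -> (n, p) array`` supplies baseline
    covariates named by ``covariate_names``.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    if not 0.0 <= genotyped_fraction <= 1.0:
        raise ConfigurationError("genotyped_fraction must lie in [0, 1]")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) \
        else rng
    covariate_names = tuple(covariate_names)
    Xall = None
    if covariate_sampler is not None:
        Xall = np.asarray(covariate_sampler(rng, n), dtype=float).reshape(n, -1)
        if Xall.shape[1] != len(covariate_names):
            raise ConfigurationError("covariate_sampler width != covariate_names")
    is_mix = isinstance(model, MixtureModel)
    components = model.components if is_mix else [model]
    K = len(components)
    t0 = float(scheme.exam_ages[0]) if t0 is None else float(t0)
    horizon = float(scheme.censor_age)

    if is_mix:
        if model.membership_covariates:
            idx = [covariate_names.index(c) for c in model.membership_covariates]
            X0 = Xall[:, idx]
        else:
            X0 = None
        P = np.atleast_2d(class_probabilities(model, X0))
        if P.shape[0] == 1:
            P = np.broadcast_to(P, (n, K))
        labels = 1 + (rng.random((n, 1)) > np.cumsum(P, axis=1)[:, :-1]).sum(axis=1)
    else:
        labels = np.ones(n, dtype=int)

    # planned examination ages per individual (jitter + missingness)
    base = scheme.exam_ages
    planned = np.broadcast_to(base, (n, base.size)).copy()
    if scheme.jitter_sd > 0:
        jit = rng.standard_normal((n, base.size)) * scheme.jitter_sd
        jit[:, 0] = 0.0                      # entry examination stays at entry
        planned = planned + jit
    keep_plan = np.ones((n, base.size), dtype=bool)
    if scheme.miss_prob > 0:
        keep_plan = rng.random((n, base.size)) >= scheme.miss_prob
        keep_plan[:, 0] = True               # baseline exam always done
    me = None
    if scheme.measurement_sd > 0:
        me = rng.standard_normal((n, base.size, components[0].dim)) \
            * scheme.measurement_sd

    tau = np.empty(n)
    delta = np.empty(n, dtype=np.int8)
    n_steps = int(np.ceil((horizon - t0) / dt - 1e-9))
    grid = t0 + dt * np.arange(n_steps + 1)
    obs_store = np.empty((n, base.size, components[0].dim))
    obs_steps = np.clip(np.round((planned - t0) / dt).astype(int), 0, n_steps)
    for k in range(1, K + 1):
        sel = labels == k
        if not sel.any():
            continue
        params_k = components[k - 1]
        p = len(params_k.covariates)
        Xk = None
        if p:
            idx = [covariate_names.index(c) for c in params_k.covariates]
            Xk = Xall[sel][:, idx]
        _, paths, tau_k, delta_k = _simulate_paths(
            params_k, int(sel.sum()), t0, horizon, dt, rng, X=Xk,
            keep_path=True)
        tau[sel] = tau_k
        delta[sel] = delta_k
        rows = np.arange(int(sel.sum()))
        obs_store[sel] = np.transpose(
            paths[obs_steps[sel].T, rows[None, :], :], (1, 0, 2))

    genotyped = rng.random(n) < genotyped_fraction
    individuals = []
    for i in range(n):
        ages = t0 + obs_steps[i] * dt
        ok = keep_plan[i] & (ages <= tau[i] + 1e-12)
        ages_i, order = np.unique(ages[ok], return_index=True)
        vals_i = obs_store[i][ok][order]
        if me is not None:
            vals_i = vals_i + me[i][ok][order]
        individuals.append(Individual(
            id=i, t0=t0, tau=float(tau[i]), delta=int(delta[i]),
            obs_ages=ages_i, obs_values=vals_i,
            x=Xall[i] if Xall is not None else np.empty(0),
            genotype=int(labels[i]) if (is_mix and genotyped[i]) else None))
    return Cohort(individuals, covariate_names, truth=model, seed=seed_record,
                  true_classes=labels if is_mix else None)


def mc_survival(params, n_paths: int, t0: float, horizon: float,
                grid_ages, dt: float = 0.05, rng=None, x=None, y0=None):
    """Monte-Carlo marginal survival at ``grid_ages`` with binomial SEs.

    The oracle counterpart of :func:`spmaging.likelihood.marginal_survival`.
    Returns ``(S_hat, se)``."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) \
        else rng
    p = len(params.covariates)
    X = None
    if p:
        X = np.broadcast_to(np.asarray(x, dtype=float).reshape(1, p),
                            (n_paths, p))
    y0v = None if y0 is None else np.broadcast_to(
        np.asarray(y0, dtype=float).reshape(1, params.dim), (n_paths, params.dim))
    _, _, tau, delta = _simulate_paths(params, n_paths, t0, horizon, dt, rng,
                                       X=X, y0=y0v, keep_path=False)
    grid_ages = np.asarray(grid_ages, dtype=float)
    died = delta.astype(bool)
    S = np.array([(tau > a).mean() + ((tau == a) & ~died).mean()
                  for a in grid_ages])
    se = np.sqrt(np.maximum(S * (1 - S), 1e-12) / n_paths)
    return S, se
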