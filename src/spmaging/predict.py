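"""Dynamic individual prediction and microsimulation population forecasting.

Individual prediction conditions on an individual's examination history up
to an age s: the moment state is initialised at the last observation,
propagated forward through the moment ODEs, and the conditional survival is
S(u|s) = exp(-int_s^u mubar).  Re-running the prediction after a new
measurement is the dynamic-update path.  For mixture models the prediction
averages regime-specific curves with posterior membership weights (or the
degenerate posterior at an observed genotype).

Population forecasting aggregates simulated life histories.  "What-if"
scenarios modify model components from a start age (e.g. halve the hazard
curvature Q to emulate improved stress resistance); baseline and scenario
arms reuse the same random-number stream (common random numbers), so
contrasts are paired and a null scenario reproduces the baseline arm
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import Cohort, Individual
from .latent import posterior_class
from .likelihood import _adaptive_segment, _ode_rhs, _pack_state, _unpack_state
from .mixture import MixtureModel
from .params import ConfigurationError, SPMParameters
from .simulate import _simulate_paths

__all__ = ["ScenarioSpec", "Modification", "PredictionResult",
           "predict_individual", "predict_latent", "forecast_population",
           "apply_scenario"]

_MODIFIABLE = ("a", "f1", "f0", "B", "Q", "mu0")


@dataclass
class Modification:
    """One component change: ``Q *= 0.5`` is ``Modification("Q", "scale", 0.5)``."""

    component: str
    op: str                      # "scale" | "shift"
    value: float
    from_age: float | None = None

    def __post_init__(self) -> None:
        if self.component not in _MODIFIABLE:
            raise ConfigurationError(
                f"unknown component {self.component!r}; expected one of "
                f"{_MODIFIABLE}")
        if self.op not in ("scale", "shift"):
            raise ConfigurationError("op must be 'scale' or 'shift'")


@dataclass
class ScenarioSpec:
    """A named set of component modifications applied from a start age."""

    name: str
    modifications: list[Modification] = field(default_factory=list)
    start_age: float | None = None


class _ModifiedParams:
    """Duck-typed parameter object whose component evaluation applies the
    scenario modifications; accepted everywhere the numerical core only
    needs ``components()`` plus the initial law."""

    def __init__(self, base: SPMParameters, scenario: ScenarioSpec):
        self._base = base
        self._scenario = scenario
        self.dim = base.dim
        self.covariates = base.covariates
        self.m0 = base.m0
        self.gamma0 = base.gamma0
        self.age_range = base.age_range

    def components(self, t, X=None):
        t = np.atleast_1d(np.asarray(t, dtype=float))
        c = dict(self._base.components(t, X))
        for mod in self._scenario.modifications:
            a0 = mod.from_age if mod.from_age is not None \
                else self._scenario.start_age
            on = np.ones(t.shape[0], dtype=bool) if a0 is None else (t >= a0)
            if not on.any():
                continue
            key = mod.component
            arr = c[key].copy()
            w = on[:, None, None] if arr.ndim == 3 else (
                on[:, None] if arr.ndim == 2 else on)
            if mod.op == "scale":
                arr = np.where(w, arr * mod.value, arr)
            else:
                arr = np.where(w, arr + mod.value, arr)
            c[key] = arr
            if key == "B":
                c["BBt"] = np.einsum("mij,mkj->mik", arr, arr)
        return c

    def check_age(self, t):
        self._base.check_age(t)


def apply_scenario(params, scenario: ScenarioSpec | None):
    """Wrap a parameter set (or each regime of a mixture) with a scenario.

    The modified model is validated on a grid over its age range: the
    hazard matrix must stay non-negative-definite and the baseline hazard
    non-negative, otherwise a configuration error is raised."""
    if scenario is None or not scenario.modifications:
        return params
    if isinstance(params, MixtureModel):
        out = params.copy()
        out.components = [apply_scenario(c, scenario) for c in params.components]
        return out
    mod = _ModifiedParams(params, scenario)
    grid = np.linspace(params.age_range[0], params.age_range[1], 101)
    p = len(params.covariates)
    X = np.zeros((grid.size, p)) if p else None
    c = mod.components(grid, X)
    if np.min(np.linalg.eigvalsh(c["Q"])) < -1e-10:
        raise ConfigurationError(
            f"scenario {scenario.name!r} makes Q indefinite on the age range")
    if np.any(c["mu0"] < 0):
        raise ConfigurationError(
            f"scenario {scenario.name!r} makes mu0 negative on the age range")
    return mod


@dataclass
class PredictionResult:
    """Conditional survival and biomarker forecast for one individual."""

    id: object
    s: float                      # conditioning age
    ages: np.ndarray              # horizon grid (starts at s)
    survival: np.ndarray          # S(u|s)
    mean: np.ndarray              # E[Y_u | history, survival], (n, J)
    var: np.ndarray               # conditional variance, (n, J, J)

    def band(self, z: float = 1.96):
        """Conditional-Gaussian band mean +/- z*sqrt(var) (approximation:
        the true conditional law is only approximately Gaussian)."""
        sd = np.sqrt(np.maximum(np.einsum("nii->ni", self.var), 0.0))
        return self.mean - z * sd, self.mean + z * sd

    def plot(self, ax=None, biomarker: int = 0):
        """Plot conditional survival (right axis) and the biomarker forecast
        with its Gaussian band (left axis) against age."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        lo, hi = self.band()
        ax.plot(self.ages, self.mean[:, biomarker], color="C0",
                label="expected biomarker")
        ax.fill_between(self.ages, lo[:, biomarker], hi[:, biomarker],
                        color="C0", alpha=0.2, label="95% band")
        ax.set_xlabel("age (years)")
        ax.set_ylabel("biomarker")
        ax2 = ax.twinx()
        ax2.plot(self.ages, self.survival, color="C3", label="S(u | s)")
        ax2.set_ylabel("conditional survival")
        ax2.set_ylim(0, 1.05)
        ax.set_title(f"individual {self.id}: prediction from age {self.s:.1f}")
        return ax


def predict_individual(params: SPMParameters, ind: Individual,
                       s: float | None = None, horizon: float = None,
                       grid=None, rtol: float = 1e-10,
                       atol: float = 1e-12) -> PredictionResult:
    """Conditional survival S(u|s) and expected trajectory given the
    individual's observations up to age ``s`` (default: last examination).

    Re-calling after appending a new observation at s' > s is the dynamic
    update path."""
    if ind.obs_ages.size == 0:
        raise ConfigurationError("prediction needs at least one observation")
    s = float(ind.obs_ages[-1]) if s is None else float(s)
    hist = ind.history_up_to(s)
    if grid is None:
        if horizon is None:
            raise ConfigurationError("need a horizon or an explicit grid")
        grid = np.linspace(s, horizon, 101)
    grid = np.asarray(grid, dtype=float)
    if abs(grid[0] - s) > 1e-9:
        grid = np.concatenate([[s], grid[grid > s]])
    p = len(params.covariates)
    X = np.asarray(hist.x, dtype=float).reshape(1, -1)[:, :p] if p else None
    t_last = float(hist.obs_ages[-1])
    m = hist.obs_values[-1].astype(float)
    G = np.zeros((params.dim, params.dim))
    if s > t_last + 1e-12:      # propagate through the data-free gap
        m, G, _, _ = _adaptive_segment(params, X, t_last, s, m, G, rtol, atol)
    from scipy.integrate import solve_ivp
    J = params.dim
    sol = solve_ivp(_ode_rhs(params, X), (s, grid[-1]),
                    _pack_state(m, G, 0.0), args=(J,), method="RK45",
                    rtol=rtol, atol=atol, t_eval=grid)
    if not sol.success:
        raise ConfigurationError(f"prediction ODE failed: {sol.message}")
    means = np.empty((grid.size, J))
    var = np.empty((grid.size, J, J))
    for i in range(grid.size):
        mi, Gi, _ = _unpack_state(sol.y[:, i], J)
        means[i], var[i] = mi, Gi
    S = np.exp(-np.maximum(sol.y[-1], 0.0))
    return PredictionResult(ind.id, s, grid, S, means, var)


def predict_latent(model: MixtureModel, ind: Individual,
                   s: float | None = None, horizon: float = None,
                   grid=None) -> PredictionResult:
    """Mixture prediction: posterior-weighted average of regime-specific
    predictions, with the posterior degenerate at an observed genotype.

    The membership posterior conditions on the history up to ``s`` and on
    survival to ``s``; the survival curve is sum_k post_k S_k(u|s) and the
    biomarker forecast mixes regime means and variances accordingly."""
    s = float(ind.obs_ages[-1]) if s is None else float(s)
    K = model.K
    if ind.genotype is not None:
        post = np.zeros(K)
        post[int(ind.genotype) - 1] = 1.0
    else:
        post = posterior_class(model, ind.history_up_to(s))
    preds = [predict_individual(c, ind, s=s, horizon=horizon, grid=grid)
             for c in model.components]
    S = sum(post[k] * preds[k].survival for k in range(K))
    mean = sum(post[k] * preds[k].mean for k in range(K))
    var = sum(post[k] * (preds[k].var
                         + np.einsum("ni,nj->nij", preds[k].mean - mean,
                                     preds[k].mean - mean))
              for k in range(K))
    return PredictionResult(ind.id, s, preds[0].ages, S, mean, var)


def forecast_population(model, entry_age: float, horizon: float,
                        n_sim: int = 10000, scenario: ScenarioSpec | None = None,
                        seed: int = 0, dt: float = 0.05, grid=None,
                        covariate_sampler=None, covariate_names=(),
                        common_random_numbers: bool = True) -> pd.DataFrame:
    """Microsimulation projection of survival, mean biomarker levels and
    cumulative deaths, baseline vs scenario side by side.

    Both arms simulate ``n_sim`` life histories; with common random numbers
    (default) the arms share one seeded stream so contrasts are paired and
    a null scenario reproduces the baseline columns exactly.  Columns:
    ``age``, then per arm ``survival``, ``survival_se``, ``mean_y``,
    ``cum_deaths``."""
    if n_sim < 1:
        raise ConfigurationError("n_sim must be >= 1")
    if grid is None:
        grid = np.linspace(entry_age, horizon, 21)
    grid = np.asarray(grid, dtype=float)
    steps = np.round((grid - entry_age) / dt).astype(int)
    arms = {"base": model}
    if scenario is not None:
        arms[scenario.name] = apply_scenario(model, scenario)
    out = pd.DataFrame({"age": entry_age + steps * dt})
    med = {}
    for arm_name, arm_model in arms.items():
        rng = np.random.default_rng(
            seed if common_random_numbers else
            seed + (0 if arm_name == "base" else 1))
        rec, tau, delta = _simulate_arm(arm_model, n_sim, entry_age, horizon,
                                        dt, rng, steps, covariate_sampler,
                                        covariate_names)
        ages = out["age"].to_numpy()
        alive = tau[None, :] >= ages[:, None] - 1e-12
        S = alive.mean(axis=1)
        ybar = np.array([rec[i, alive[i], 0].mean() if alive[i].any() else np.nan
                         for i in range(ages.size)])
        deaths = np.array([(delta.astype(bool) & (tau < a + 1e-12)).sum()
                           for a in ages])
        out[f"survival_{arm_name}"] = S
        out[f"survival_se_{arm_name}"] = np.sqrt(
            np.maximum(S * (1 - S), 1e-12) / n_sim)
        out[f"mean_y_{arm_name}"] = ybar
        out[f"cum_deaths_{arm_name}"] = deaths
        med[arm_name] = float(np.median(tau))
    out.attrs["n_sim"] = n_sim
    out.attrs["seed"] = seed
    out.attrs["median_lifetime"] = med
    return out


def _simulate_arm(model, n, t0, horizon, dt, rng, steps, sampler, names):
    """One forecasting arm; handles mixtures by drawing regimes first."""
    X = None
    if sampler is not None:
        X = np.asarray(sampler(rng, n), dtype=float).reshape(n, -1)
    if isinstance(model, MixtureModel):
        from .mixture import class_probabilities
        X0 = None
        if model.membership_covariates:
            idx = [tuple(names).index(c) for c in model.membership_covariates]
            X0 = X[:, idx]
        P = np.atleast_2d(class_probabilities(model, X0))
        if P.shape[0] == 1:
            P = np.broadcast_to(P, (n, model.K))
        labels = 1 + (rng.random((n, 1)) > np.cumsum(P, axis=1)[:, :-1]).sum(axis=1)
        rec = np.empty((steps.size, n, model.dim))
        tau = np.empty(n)
        delta = np.empty(n, dtype=np.int8)
        for k in range(1, model.K + 1):
            sel = labels == k
            if not sel.any():
                continue
            comp = model.components[k - 1]
            Xk = None
            if getattr(comp, "covariates", ()):
                idx = [tuple(names).index(c) for c in comp.covariates]
                Xk = X[sel][:, idx]
            _, r, t_, d_ = _simulate_paths(comp, int(sel.sum()), t0, horizon,
                                           dt, rng, X=Xk, record_steps=steps)
            rec[:, sel], tau[sel], delta[sel] = r, t_, d_
        return rec, tau, delta
    Xm = None
    if getattr(model, "covariates", ()):
        idx = [tuple(names).index(c) for c in model.covariates]
        Xm = X[:, idx]
    _, rec, tau, delta = _simulate_paths(model, n, t0, horizon, dt, rng,
                                         X=Xm, record_steps=steps)
    return rec, tau, delta
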