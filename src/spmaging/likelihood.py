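"""Continuous-time SPM likelihood via conditional-Gaussian moment equations.

Between examinations the conditional law of the latent biomarker vector
Y_t — given survival to t and the observation history — is approximated as
Gaussian with mean m(t) and covariance gamma(t) obeying

    dm/dt     = a (m - f1) - 2 gamma Q (m - f0)
    dgamma/dt = a gamma + gamma a' + B B' - 2 gamma Q gamma

(the quadratic-hazard conditioning pulls m toward the physiological norm f0
and shrinks gamma; with Q = 0 these are the unconditional OU moment
equations).  The population-averaged hazard under that law is

    mubar(t) = mu0 + (m - f0)' Q (m - f0) + tr(Q gamma),

and an individual's log-likelihood contribution factorises into one-step-
ahead Gaussian observation densities, the survival exponent
-int_{t0}^{tau} mubar dt, and delta * log mubar(tau-).

With exact observations (the default — no measurement-error term in the
SDE) the state resets to (m = y, gamma = 0) at each examination, which makes
all inter-observation intervals conditionally independent; the default
solver exploits this by propagating every interval of the whole cohort
simultaneously with a fixed-step classical RK4 scheme (step <= ``h_target``
years).  An adaptive solve_ivp path (RK45, rtol 1e-8) is available via
``solver="adaptive"`` and is the reference for accuracy checks; marginal
survival always uses the adaptive solver.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .data import Cohort, Individual, DataError
from .params import SPMParameters, ConfigurationError

__all__ = [
    "MomentState", "moment_derivatives", "conditional_hazard",
    "individual_loglik", "cohort_loglik", "individual_logliks",
    "marginal_survival", "discrete_time_loglik", "prepare_cohort",
    "propagate_moments",
]

_GAMMA_TOL = -1e-10
_FLOOR = 1e-300


class LikelihoodError(ValueError):
    pass


@dataclass
class MomentState:
    """Conditional mean and covariance of Y_t given survival + history."""

    t: float
    m: np.ndarray
    gamma: np.ndarray

    def __post_init__(self) -> None:
        self.m = np.atleast_1d(np.asarray(self.m, dtype=float))
        self.gamma = np.asarray(self.gamma, dtype=float)
        if self.gamma.ndim == 0:
            self.gamma = self.gamma.reshape(1, 1)
        J = self.m.size
        if self.gamma.shape != (J, J):
            raise ConfigurationError("gamma must be J x J")
        if not np.all(np.isfinite(self.m)):
            raise ConfigurationError("m must be finite")
        w = np.linalg.eigvalsh((self.gamma + self.gamma.T) / 2)
        if w.min() < _GAMMA_TOL:
            raise ConfigurationError(f"gamma not PSD (eigenvalue {w.min():.3g})")


def _derivs(params, t, X, m, G):
    """Vectorised moment derivatives + mean hazard for a batch of states.

    t: (M,); X: (M,p) or None; m: (M,J); G: (M,J,J).
    Returns (dm, dG, mubar)."""
    c = params.components(t, X)
    d1 = m - c["f1"]
    d0 = m - c["f0"]
    Q = c["Q"]
    A = c["a"]
    Qd0 = np.einsum("mij,mj->mi", Q, d0)
    dm = np.einsum("mij,mj->mi", A, d1) - 2.0 * np.einsum("mij,mj->mi", G, Qd0)
    AG = np.einsum("mij,mjk->mik", A, G)
    GQ = np.einsum("mij,mjk->mik", G, Q)
    dG = AG + np.swapaxes(AG, 1, 2) + c["BBt"] - 2.0 * np.einsum(
        "mij,mjk->mik", GQ, G)
    mubar = c["mu0"] + np.einsum("mi,mi->m", d0, Qd0) + np.einsum(
        "mii->m", GQ)
    return dm, dG, mubar


def moment_derivatives(params: SPMParameters, x, state: MomentState):
    """(dm/dt, dgamma/dt) at a single state — the moment ODE right-hand side."""
    p = len(params.covariates)
    X = None if p == 0 else np.asarray(x, dtype=float).reshape(1, p)
    dm, dG, _ = _derivs(params, np.array([state.t]), X,
                        state.m[None], state.gamma[None])
    return dm[0], dG[0]


def conditional_hazard(params: SPMParameters, x, state: MomentState) -> float:
    """Mean hazard mubar(t) = mu0 + (m-f0)'Q(m-f0) + tr(Q gamma)."""
    p = len(params.covariates)
    X = None if p == 0 else np.asarray(x, dtype=float).reshape(1, p)
    _, _, mu = _derivs(params, np.array([state.t]), X,
                       state.m[None], state.gamma[None])
    return float(mu[0])


# ----------------------------------------------------------------------
# cohort preprocessing: independent inter-observation segments
# ----------------------------------------------------------------------

class _Prepared:
    """Flattened segment table for the vectorised likelihood.

    Each segment runs from one state reset to the next boundary.  Exact
    observations make segments independent: a segment starts either from a
    just-observed state (m = y, gamma = 0) or, for a pre-first-observation
    segment, from the initial law (filled in per parameter value)."""

    __slots__ = ("owner", "t0", "t1", "m0", "law_mask", "has_obs", "y_end",
                 "terminal", "delta_term", "X", "n_ind", "J", "n_density",
                 "cov_idx")

    def __init__(self, cohort: Cohort, J: int, cov_idx):
        owner, t0s, t1s, m0s, law, has_obs, y_end, term, delt = \
            [], [], [], [], [], [], [], [], []
        for i, ind in enumerate(cohort):
            ages = ind.obs_ages
            vals = ind.obs_values
            if ages.size == 0:
                owner.append(i); t0s.append(ind.t0); t1s.append(ind.tau)
                m0s.append(np.zeros(J)); law.append(True)
                has_obs.append(False); y_end.append(np.zeros(J))
                term.append(True); delt.append(ind.delta)
                continue
            if ages[0] > ind.t0 + 1e-9:
                owner.append(i); t0s.append(ind.t0); t1s.append(ages[0])
                m0s.append(np.zeros(J)); law.append(True)
                has_obs.append(True); y_end.append(vals[0])
                term.append(False); delt.append(0)
            for j in range(ages.size - 1):
                owner.append(i); t0s.append(ages[j]); t1s.append(ages[j + 1])
                m0s.append(vals[j]); law.append(False)
                has_obs.append(True); y_end.append(vals[j + 1])
                term.append(False); delt.append(0)
            owner.append(i); t0s.append(ages[-1]); t1s.append(ind.tau)
            m0s.append(vals[-1]); law.append(False)
            has_obs.append(False); y_end.append(np.zeros(J))
            term.append(True); delt.append(ind.delta)
        self.owner = np.array(owner, dtype=np.intp)
        self.t0 = np.array(t0s); self.t1 = np.array(t1s)
        self.m0 = np.array(m0s).reshape(-1, J)
        self.law_mask = np.array(law, dtype=bool)
        self.has_obs = np.array(has_obs, dtype=bool)
        self.y_end = np.array(y_end).reshape(-1, J)
        self.terminal = np.array(term, dtype=bool)
        self.delta_term = np.array(delt, dtype=float)
        self.n_ind = len(cohort)
        self.J = J
        self.n_density = int(self.has_obs.sum())
        self.cov_idx = cov_idx
        if cov_idx is not None:
            Xi = np.array([ind.x[cov_idx] for ind in cohort], dtype=float)
            self.X = Xi[self.owner]
        else:
            self.X = None


def _covariate_indices(cohort: Cohort, params: SPMParameters):
    if not params.covariates:
        return None
    if not cohort.covariate_names:
        raise ConfigurationError(
            f"model needs covariates {params.covariates} but cohort has none")
    try:
        return np.array([cohort.covariate_names.index(c)
                         for c in params.covariates], dtype=np.intp)
    except ValueError as e:
        raise ConfigurationError(f"covariate missing from cohort: {e}")


def prepare_cohort(cohort: Cohort, params: SPMParameters) -> _Prepared:
    """Precompute the segment table; reusable across likelihood evaluations
    with different parameter values (same structure)."""
    return _Prepared(cohort, params.dim, _covariate_indices(cohort, params))


def _rk4_batch(params, X, t0, t1, m, G, n_steps):
    """Classical RK4 on (m, gamma, Lambda) for a batch of segments sharing
    the same step count.  Returns (m, G, Lam, mu_end)."""
    M, J = m.shape
    h = (t1 - t0) / n_steps
    Lam = np.zeros(M)
    t = t0.copy()
    hh = h[:, None]
    hhh = h[:, None, None]
    for _ in range(n_steps):
        k1m, k1G, k1L = _derivs(params, t, X, m, G)
        k2m, k2G, k2L = _derivs(params, t + h / 2, X,
                                m + 0.5 * hh * k1m, G + 0.5 * hhh * k1G)
        k3m, k3G, k3L = _derivs(params, t + h / 2, X,
                                m + 0.5 * hh * k2m, G + 0.5 * hhh * k2G)
        k4m, k4G, k4L = _derivs(params, t + h, X,
                                m + hh * k3m, G + hhh * k3G)
        m = m + hh / 6 * (k1m + 2 * k2m + 2 * k3m + k4m)
        G = G + hhh / 6 * (k1G + 2 * k2G + 2 * k3G + k4G)
        Lam = Lam + h / 6 * (k1L + 2 * k2L + 2 * k3L + k4L)
        if J == 1:
            np.maximum(G, 0.0, out=G)
        else:
            G = (G + np.swapaxes(G, 1, 2)) / 2
        t = t + h
    _, _, mu_end = _derivs(params, t1, X, m, G)
    return m, G, Lam, mu_end


def _check_psd(G, context: str):
    J = G.shape[-1]
    if J == 1:
        bad = G[:, 0, 0] < _GAMMA_TOL
        if bad.any():
            warnings.warn(f"gamma clipped to PSD during {context} "
                          f"(min {G[:, 0, 0].min():.3g})", RuntimeWarning)
        return np.maximum(G, 0.0)
    w, V = np.linalg.eigh((G + np.swapaxes(G, 1, 2)) / 2)
    if w.min() < _GAMMA_TOL:
        warnings.warn(f"gamma clipped to PSD during {context} "
                      f"(min eigenvalue {w.min():.3g})", RuntimeWarning)
    w = np.maximum(w, 0.0)
    return np.einsum("mij,mj,mkj->mik", V, w, V)


def _gauss_logpdf(y, m, G):
    """Batched Gaussian log-density with degenerate-covariance detection."""
    J = y.shape[1]
    r = y - m
    if J == 1:
        v = G[:, 0, 0]
        if np.any(v <= 0):
            raise LikelihoodError(
                "degenerate one-step-ahead density (zero conditional variance; "
                "duplicated observation age or zero diffusion?)")
        return -0.5 * (np.log(2 * np.pi * v) + r[:, 0] ** 2 / v)
    try:
        L = np.linalg.cholesky(G)
    except np.linalg.LinAlgError:
        raise LikelihoodError("degenerate one-step-ahead density (singular "
                              "conditional covariance)")
    z = np.linalg.solve(L, r[:, :, None])[:, :, 0]
    logdet = 2 * np.log(np.einsum("mii->mi", L)).sum(axis=1)
    return -0.5 * (J * np.log(2 * np.pi) + logdet + (z ** 2).sum(axis=1))


try:                      # scalar-model fast path; numpy path covers J > 1
    from numba import njit as _njit
    _HAVE_NUMBA = True
except ImportError:       # pragma: no cover - numba is a hard dependency
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def deco(f):
            return f
        return deco


@_njit(cache=True)
def _rk4_j1_kernel(t0, t1, m0, g0, steps,
                   a0, a1, f10, f11, f00, f01, bb, q0, q1, c0, th,
                   s1, s0, lmu):
    """Per-segment RK4 for the scalar model (J = 1).

    s1, s0, lmu are the per-segment covariate shifts on f1, f0 and the
    log-multiplier on mu0.  Returns (m_end, g_end, Lambda, mu_end)."""
    M = t0.shape[0]
    m_end = np.empty(M)
    g_end = np.empty(M)
    lam = np.empty(M)
    mu_end = np.empty(M)
    for i in range(M):
        n = steps[i]
        h = (t1[i] - t0[i]) / n
        m = m0[i]
        g = g0[i]
        L = 0.0
        for k in range(n):
            tk = t0[i] + k * h
            # classical RK4 on (m, gamma, Lambda), stages unrolled
            t = tk
            at = a0 + a1 * t
            qt = q0 * max(1.0 + q1 * t, 0.0)
            d1 = m - (f10 + f11 * t + s1[i])
            d0 = m - (f00 + f01 * t + s0[i])
            km1 = at * d1 - 2.0 * g * qt * d0
            kg1 = 2.0 * at * g + bb - 2.0 * g * g * qt
            kl1 = np.exp(c0 + th * t + lmu[i]) + qt * (d0 * d0 + g)

            t = tk + 0.5 * h
            mm = m + 0.5 * h * km1
            gg = g + 0.5 * h * kg1
            at = a0 + a1 * t
            qt = q0 * max(1.0 + q1 * t, 0.0)
            d1 = mm - (f10 + f11 * t + s1[i])
            d0 = mm - (f00 + f01 * t + s0[i])
            km2 = at * d1 - 2.0 * gg * qt * d0
            kg2 = 2.0 * at * gg + bb - 2.0 * gg * gg * qt
            kl2 = np.exp(c0 + th * t + lmu[i]) + qt * (d0 * d0 + gg)

            mm = m + 0.5 * h * km2
            gg = g + 0.5 * h * kg2
            d1 = mm - (f10 + f11 * t + s1[i])
            d0 = mm - (f00 + f01 * t + s0[i])
            km3 = at * d1 - 2.0 * gg * qt * d0
            kg3 = 2.0 * at * gg + bb - 2.0 * gg * gg * qt
            kl3 = np.exp(c0 + th * t + lmu[i]) + qt * (d0 * d0 + gg)

            t = tk + h
            mm = m + h * km3
            gg = g + h * kg3
            at = a0 + a1 * t
            qt = q0 * max(1.0 + q1 * t, 0.0)
            d1 = mm - (f10 + f11 * t + s1[i])
            d0 = mm - (f00 + f01 * t + s0[i])
            km4 = at * d1 - 2.0 * gg * qt * d0
            kg4 = 2.0 * at * gg + bb - 2.0 * gg * gg * qt
            kl4 = np.exp(c0 + th * t + lmu[i]) + qt * (d0 * d0 + gg)

            m = m + h / 6.0 * (km1 + 2 * km2 + 2 * km3 + km4)
            g = g + h / 6.0 * (kg1 + 2 * kg2 + 2 * kg3 + kg4)
            if g < 0.0:
                g = 0.0
            L = L + h / 6.0 * (kl1 + 2 * kl2 + 2 * kl3 + kl4)
        m_end[i] = m
        g_end[i] = g
        lam[i] = L
        t = t1[i]
        at = a0 + a1 * t
        qt = q0 * max(1.0 + q1 * t, 0.0)
        d0 = m - (f00 + f01 * t + s0[i])
        mu_end[i] = np.exp(c0 + th * t + lmu[i]) + qt * (d0 * d0 + g)
    return m_end, g_end, lam, mu_end


def _j1_shifts(params, X, M):
    """Covariate shifts (f1, f0, log mu0) per segment for the scalar kernel."""
    if X is None:
        z = np.zeros(M)
        return z, z, z
    return (X @ params.f1_x.T)[:, 0], (X @ params.f0_x.T)[:, 0], X @ params.mu0_x


def _segment_steps(dt, h_target):
    """Per-segment RK4 step counts, quantised to powers of two so the whole
    cohort propagates in at most ~11 equal-step batches."""
    need = np.maximum(dt / h_target, 1.0)
    return np.power(2, np.ceil(np.log2(need) - 1e-12)).astype(int).clip(1, 1024)


def individual_logliks(params: SPMParameters, cohort: Cohort,
                       prepared: _Prepared | None = None,
                       h_target: float = 0.25,
                       solver: str = "rk4") -> np.ndarray:
    """Per-individual log-likelihood contributions (shape (n,))."""
    prep = prepared if prepared is not None else prepare_cohort(cohort, params)
    J = prep.J
    M = prep.owner.size
    m0 = prep.m0.copy()
    G0 = np.zeros((M, J, J))
    if prep.law_mask.any():
        m0[prep.law_mask] = params.m0
        G0[prep.law_mask] = params.gamma0
    dt = prep.t1 - prep.t0
    if np.any(dt < -1e-9):
        raise DataError("negative integration step (observation ordering)")
    m_end = np.empty_like(m0)
    G_end = np.empty_like(G0)
    Lam = np.zeros(M)
    mu_end = np.empty(M)
    if solver == "adaptive":
        for i in range(M):
            Xi = None if prep.X is None else prep.X[i:i + 1]
            m_end[i], G_end[i], Lam[i], mu_end[i] = _adaptive_segment(
                params, Xi, prep.t0[i], prep.t1[i], m0[i], G0[i])
    elif J == 1 and _HAVE_NUMBA:
        steps = np.ceil(np.maximum(dt / h_target, 1.0) - 1e-9).astype(np.int64)
        s1, s0, lmu = _j1_shifts(params, prep.X, M)
        me, ge, Lam, mu_end = _rk4_j1_kernel(
            prep.t0, prep.t1, m0[:, 0], G0[:, 0, 0], steps,
            float(params.a0[0, 0]), float(params.a1[0, 0]),
            float(params.f1_0[0]), float(params.f1_1[0]),
            float(params.f0_0[0]), float(params.f0_1[0]),
            float(params.b[0] ** 2), float(params.Q0[0, 0]), float(params.q1),
            float(params.mu0_c0), float(params.mu0_theta),
            np.ascontiguousarray(s1), np.ascontiguousarray(s0),
            np.ascontiguousarray(lmu))
        m_end = me[:, None]
        G_end = ge[:, None, None]
        zero = dt <= 1e-12
        Lam[zero] = 0.0
    else:
        steps = _segment_steps(dt, h_target)
        zero = dt <= 1e-12
        if zero.any():
            m_end[zero] = m0[zero]
            G_end[zero] = G0[zero]
            Xz = None if prep.X is None else prep.X[zero]
            _, _, mu_end[zero] = _derivs(params, prep.t1[zero], Xz,
                                         m0[zero], G0[zero])
            Lam[zero] = 0.0
        for s in np.unique(steps[~zero]):
            sel = (~zero) & (steps == s)
            Xs = None if prep.X is None else prep.X[sel]
            m_end[sel], G_end[sel], Lam[sel], mu_end[sel] = _rk4_batch(
                params, Xs, prep.t0[sel], prep.t1[sel], m0[sel], G0[sel], int(s))
    G_end = _check_psd(G_end, "likelihood propagation")
    with np.errstate(invalid="ignore", over="ignore", divide="ignore"):
        ll_seg = -Lam
        if prep.has_obs.any():
            ll_seg[prep.has_obs] += _gauss_logpdf(
                prep.y_end[prep.has_obs], m_end[prep.has_obs],
                G_end[prep.has_obs])
        ev = prep.terminal & (prep.delta_term > 0)
        ll_seg[ev] += np.log(np.maximum(mu_end[ev], _FLOOR))
        out = np.bincount(prep.owner, weights=ll_seg, minlength=prep.n_ind)
    return out


def cohort_loglik(params: SPMParameters, cohort: Cohort,
                  prepared=None, h_target: float = 0.25,
                  solver: str = "rk4") -> float:
    """Total cohort log-likelihood (sum of individual contributions)."""
    return float(np.sum(individual_logliks(params, cohort, prepared,
                                           h_target, solver)))


def individual_loglik(params: SPMParameters, ind: Individual,
                      covariate_names=None, h_target: float = 0.25,
                      solver: str = "rk4", measurement_sd: float = 0.0) -> float:
    """Log-likelihood contribution of one individual.

    With ``measurement_sd > 0`` the hard reset at observations is replaced
    by the linear-Gaussian filter update (observations y = Y + e,
    e ~ N(0, sd^2 I))."""
    names = tuple(covariate_names) if covariate_names else params.covariates
    cohort = Cohort([ind], covariate_names=names)
    if measurement_sd > 0:
        return _loglik_filtered(params, cohort, measurement_sd)
    return float(individual_logliks(params, cohort, solver=solver,
                                    h_target=h_target)[0])


# ----------------------------------------------------------------------
# adaptive reference solver (single segment / marginal survival)
# ----------------------------------------------------------------------

def _pack_state(m, G, Lam):
    J = m.size
    iu = np.triu_indices(J)
    return np.concatenate([m, G[iu], [Lam]])


def _unpack_state(z, J):
    iu = np.triu_indices(J)
    m = z[:J]
    G = np.zeros((J, J))
    G[iu] = z[J:-1]
    G = G + G.T - np.diag(np.diag(G))
    return m, G, z[-1]


def _ode_rhs(params, X):
    def rhs(t, z, J):
        m, G, _ = _unpack_state(z, J)
        dm, dG, mu = _derivs(params, np.array([t]), X, m[None], G[None])
        iu = np.triu_indices(J)
        return np.concatenate([dm[0], dG[0][iu], [mu[0]]])
    return rhs


def _adaptive_segment(params, X, t0, t1, m, G, rtol=1e-8, atol=1e-10):
    J = m.size
    if t1 - t0 <= 1e-12:
        _, _, mu = _derivs(params, np.array([t1]), X, m[None], G[None])
        return m, G, 0.0, float(mu[0])
    rhs = _ode_rhs(params, X)
    sol = solve_ivp(rhs, (t0, t1), _pack_state(m, G, 0.0), args=(J,),
                    method="RK45", rtol=rtol, atol=atol)
    if not sol.success:
        raise LikelihoodError(f"moment ODE integration failed near age "
                              f"{sol.t[-1]:.2f}: {sol.message}")
    m1, G1, Lam = _unpack_state(sol.y[:, -1], J)
    _, _, mu = _derivs(params, np.array([t1]), X, m1[None], G1[None])
    return m1, G1, Lam, float(mu[0])


def propagate_moments(params: SPMParameters, x, state: MomentState,
                      t1: float, rtol: float = 1e-10, atol: float = 1e-12):
    """Propagate the conditional moments from ``state.t`` to ``t1`` with the
    adaptive reference solver.

    Returns ``(MomentState at t1, survival factor exp(-int mubar))`` — the
    building block of the likelihood between observations."""
    p = len(params.covariates)
    X = None if p == 0 else np.asarray(x, dtype=float).reshape(1, p)
    m, G, Lam, _ = _adaptive_segment(params, X, state.t, t1,
                                     state.m.copy(), state.gamma.copy(),
                                     rtol, atol)
    return MomentState(t1, m, G), math.exp(-Lam)


def marginal_survival(params: SPMParameters, x=None, t0: float | None = None,
                      horizon: float | None = None, grid=None,
                      rtol: float = 1e-10, atol: float = 1e-12):
    """Population marginal survival S(t) = exp(-int mubar), moments started
    from the initial law (m0, gamma0) with no observation resets.

    Returns ``(ages, S)`` with S(t0) = 1, S non-increasing."""
    if grid is not None:
        grid = np.asarray(grid, dtype=float)
        t0 = grid[0] if t0 is None else t0
        horizon = grid[-1]
    if t0 is None or horizon is None:
        raise ConfigurationError("need t0 and horizon (or an explicit grid)")
    if not horizon > t0:
        raise ConfigurationError("horizon must exceed t0")
    if grid is None:
        grid = np.linspace(t0, horizon, 101)
    p = len(params.covariates)
    X = None if p == 0 else np.asarray(x, dtype=float).reshape(1, p)
    rhs = _ode_rhs(params, X)
    J = params.dim
    sol = solve_ivp(rhs, (t0, horizon),
                    _pack_state(params.m0, params.gamma0, 0.0), args=(J,),
                    method="RK45", rtol=rtol, atol=atol, t_eval=grid)
    if not sol.success:
        raise LikelihoodError(f"survival ODE failed: {sol.message}")
    Lam = sol.y[-1]
    return grid, np.exp(-np.maximum(Lam, 0.0))


# ----------------------------------------------------------------------
# measurement-error (filtered) likelihood — sequential per individual
# ----------------------------------------------------------------------

def _loglik_filtered(params, cohort, sd, rtol=1e-8, atol=1e-10):
    total = 0.0
    cov_idx = _covariate_indices(cohort, params)
    R = sd ** 2 * np.eye(params.dim)
    for ind in cohort:
        X = None if cov_idx is None else ind.x[cov_idx][None, :]
        m, G = params.m0.copy(), params.gamma0.copy()
        t = ind.t0
        ll = 0.0
        for j, (age, y) in enumerate(zip(ind.obs_ages, ind.obs_values)):
            m, G, Lam, _ = _adaptive_segment(params, X, t, age, m, G, rtol, atol)
            ll -= Lam
            S = G + R
            if not (j == 0 and age <= ind.t0 + 1e-9):
                # baseline exam at entry is conditioned on, as in the
                # exact-observation path
                ll += float(_gauss_logpdf(y[None], m[None], S[None])[0])
            K = np.linalg.solve(S.T, G.T).T          # gain gamma (gamma+R)^-1
            m = m + K @ (y - m)
            G = G - K @ G
            G = (G + G.T) / 2
            t = age
        m, G, Lam, mu = _adaptive_segment(params, X, t, ind.tau, m, G, rtol, atol)
        ll -= Lam
        if ind.delta:
            ll += math.log(max(mu, _FLOOR))
        total += ll
    return total


# ----------------------------------------------------------------------
# discrete-time likelihood
# ----------------------------------------------------------------------

def discrete_time_loglik(params: SPMParameters, cohort: Cohort,
                         step: float, bin_ages: bool = False) -> float:
    """Log-likelihood under the discrete-time SPM.

    Observation ages must lie on the ``step`` grid anchored at each
    individual's entry age (tolerance 1e-6), unless ``bin_ages`` rounds them
    to the nearest grid point.  Factors: Gaussian transitions
    N(y_{j+1}; y_j + a(t_j)(y_j - f1(t_j)) Delta, BB' Delta) between
    consecutive observations, per-step survival exp(-mu(t_j, y_j) Delta)
    with the observed state, and event factor 1 - exp(-mu Delta) at the
    event step."""
    cov_idx = _covariate_indices(cohort, params)
    total = 0.0
    for ind in cohort:
        ages = ind.obs_ages.copy()
        offs = (ages - ind.t0) / step
        if bin_ages:
            ages = ind.t0 + np.round(offs) * step
        elif np.any(np.abs(offs - np.round(offs)) > 1e-6):
            raise DataError(
                f"individual {ind.id}: observation ages off the {step}-year "
                "grid (pass bin_ages=True to bin)")
        if ages.size == 0:
            continue
        X = None if cov_idx is None else np.broadcast_to(
            ind.x[cov_idx], (ages.size, cov_idx.size))
        c = params.components(ages, X)
        y = ind.obs_values
        dev0 = y - c["f0"]
        mu = c["mu0"] + np.einsum("mi,mij,mj->m", dev0, c["Q"], dev0)
        # transitions between consecutive observations
        if ages.size > 1:
            d = np.diff(ages)
            mean = y[:-1] + np.einsum("mij,mj->mi", c["a"][:-1],
                                      y[:-1] - c["f1"][:-1]) * d[:, None]
            cov = c["BBt"][:-1] * d[:, None, None]
            total += float(_gauss_logpdf(y[1:], mean, cov).sum())
            # survival through each inter-observation step
            total += float(-(mu[:-1] * d).sum())
        # final step from last observation to tau
        d_last = ind.tau - ages[-1]
        if ind.delta:
            p_ev = 1.0 - math.exp(-mu[-1] * max(d_last, step * 1e-12))
            total += math.log(max(p_ev, _FLOOR))
        else:
            total += -mu[-1] * d_last
    return total
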