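"""Parametric components of the stochastic process model (SPM) of aging.

The model couples an Ornstein--Uhlenbeck-type stochastic differential
equation for a J-vector of biomarkers Y_t,

    dY_t = a(t, X) (Y_t - f1(t, X)) dt + B(t, X) dW_t,

with a quadratic hazard for the terminal event,

    mu(t, Y_t, X) = mu0(t, X) + (Y_t - f0(t, X))^T Q(t, X) (Y_t - f0(t, X)).

Component interpretation (aging vocabulary): ``a`` is the adaptive capacity
(negative feedback pulling Y toward the allostatic trajectory ``f1``);
``f0`` is the age-dependent physiological norm minimising the hazard;
``Q`` is the hazard curvature, inversely related to stress resistance;
``mu0`` is the baseline (Gompertz) hazard at the norm; ``B`` scales the
exogenous Wiener disturbances.

Default parametric forms (all pluggable through subclassing / the scenario
wrapper in :mod:`spmaging.predict`):

* ``a(t) = a0 + a1 t``          (J x J, default diagonal)
* ``f1(t, x) = f1_0 + f1_1 t + F1x x``
* ``f0(t, x) = f0_0 + f0_1 t + F0x x``
* ``B`` constant diagonal with entries ``b >= 0``
* ``Q(t) = Q0 * max(1 + q1 t, 0)`` with ``Q0`` symmetric NND
* ``mu0(t, x) = exp(c0 + theta t + g^T x)`` (Gompertz baseline, log-linear
  covariate multiplier)

Baseline covariates X are time-independent; by default they shift the
``f1``/``f0`` intercepts additively and multiply ``mu0``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "SPMParameters",
    "ParameterCodec",
    "evaluate_components",
    "validate_model",
    "DEFAULT_FREE",
]

#: free-parameter set of the standard scalar (J=1) model: feedback intercept
#: and slope, allostatic intercept and slope, diffusion, hazard curvature and
#: the two Gompertz coefficients.
DEFAULT_FREE = ("a0", "a1", "f1_0", "f1_1", "b", "Q0", "mu0_c0", "mu0_theta")

_FIELDS = (
    "a0", "a1", "f1_0", "f1_1", "f0_0", "f0_1", "b", "Q0", "q1",
    "mu0_c0", "mu0_theta", "m0", "gamma0", "f1_x", "f0_x", "mu0_x",
)
# transform applied coordinate-wise when packing: identity, log (positivity)
# or log-Cholesky (symmetric NND matrices)
_TRANSFORM = {name: "identity" for name in _FIELDS}
_TRANSFORM["b"] = "log"
_TRANSFORM["Q0"] = "logchol"
_TRANSFORM["gamma0"] = "logchol"


class ConfigurationError(ValueError):
    """Inconsistent model configuration (dimensions, unknown fields...)."""


class AgeRangeError(ValueError):
    """Age outside the declared model age range."""


def _as_matrix(v, J: int) -> np.ndarray:
    arr = np.asarray(v, dtype=float)
    if arr.ndim == 0:
        return np.eye(J) * float(arr)
    if arr.ndim == 1:
        if arr.size != J:
            raise ConfigurationError(f"expected {J} diagonal entries, got {arr.size}")
        return np.diag(arr)
    if arr.shape != (J, J):
        raise ConfigurationError(f"expected ({J},{J}) matrix, got {arr.shape}")
    return arr.copy()


def _as_vector(v, J: int) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(v, dtype=float))
    if arr.size == 1 and J > 1:
        arr = np.full(J, float(arr.ravel()[0]))
    if arr.shape != (J,):
        raise ConfigurationError(f"expected length-{J} vector, got shape {arr.shape}")
    return arr.copy()


@dataclass
class SPMParameters:
    """All parametric components of one SPM regime.

    Scalars are accepted everywhere and broadcast to the declared dimension
    ``dim`` (J).  ``covariates`` names the baseline covariates; the
    coefficient blocks ``f1_x``, ``f0_x`` (J x p) and ``mu0_x`` (p,) give
    their additive effect on the f1/f0 intercepts and log-linear effect on
    mu0.
    """

    dim: int = 1
    a0: np.ndarray | float = -0.1
    a1: np.ndarray | float = 0.0
    f1_0: np.ndarray | float = 0.0
    f1_1: np.ndarray | float = 0.0
    f0_0: np.ndarray | float = 0.0
    f0_1: np.ndarray | float = 0.0
    b: np.ndarray | float = 1.0
    Q0: np.ndarray | float = 0.0
    q1: float = 0.0
    mu0_c0: float = -5.0
    mu0_theta: float = 0.0
    m0: np.ndarray | float = 0.0
    gamma0: np.ndarray | float = 0.0
    covariates: tuple[str, ...] = ()
    f1_x: np.ndarray | None = None
    f0_x: np.ndarray | None = None
    mu0_x: np.ndarray | None = None
    age_range: tuple[float, float] = (0.0, 120.0)

    def __post_init__(self) -> None:
        J = int(self.dim)
        if J < 1:
            raise ConfigurationError("dim must be a positive integer")
        self.dim = J
        self.a0 = _as_matrix(self.a0, J)
        self.a1 = _as_matrix(self.a1, J)
        self.f1_0 = _as_vector(self.f1_0, J)
        self.f1_1 = _as_vector(self.f1_1, J)
        self.f0_0 = _as_vector(self.f0_0, J)
        self.f0_1 = _as_vector(self.f0_1, J)
        self.b = _as_vector(self.b, J)
        self.Q0 = _as_matrix(self.Q0, J)
        self.q1 = float(self.q1)
        self.mu0_c0 = float(self.mu0_c0)
        self.mu0_theta = float(self.mu0_theta)
        self.m0 = _as_vector(self.m0, J)
        self.gamma0 = _as_matrix(self.gamma0, J)
        self.covariates = tuple(self.covariates)
        p = len(self.covariates)
        for name in ("f1_x", "f0_x"):
            val = getattr(self, name)
            if val is None:
                val = np.zeros((J, p))
            val = np.asarray(val, dtype=float).reshape(J, p) if p else np.zeros((J, 0))
            setattr(self, name, val)
        if self.mu0_x is None:
            self.mu0_x = np.zeros(p)
        self.mu0_x = np.asarray(self.mu0_x, dtype=float).reshape(p)
        lo, hi = self.age_range
        if not lo < hi:
            raise ConfigurationError("age_range must satisfy t_min < t_max")
        self.age_range = (float(lo), float(hi))

    # ------------------------------------------------------------------
    # component evaluation (vectorised over ages)
    # ------------------------------------------------------------------
    def components(self, t: np.ndarray, X: np.ndarray | None = None) -> dict:
        """Evaluate a, f1, f0, BB^T, Q, mu0 at ages ``t`` (shape (M,)) and
        covariate rows ``X`` (shape (M, p) or None).  No range check — used
        by the numerical core; see :func:`evaluate_components` for the
        checked public entry point."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        M = t.shape[0]
        J = self.dim
        p = len(self.covariates)
        if p:
            if X is None:
                raise ConfigurationError(
                    f"model declares covariates {self.covariates} but none supplied")
            X = np.asarray(X, dtype=float).reshape(M, p)
        a = self.a0[None] + self.a1[None] * t[:, None, None]
        f1 = self.f1_0[None] + self.f1_1[None] * t[:, None]
        f0 = self.f0_0[None] + self.f0_1[None] * t[:, None]
        logmu0 = self.mu0_c0 + self.mu0_theta * t
        if p:
            f1 = f1 + X @ self.f1_x.T
            f0 = f0 + X @ self.f0_x.T
            logmu0 = logmu0 + X @ self.mu0_x
        Q = self.Q0[None] * np.maximum(1.0 + self.q1 * t, 0.0)[:, None, None]
        BBt = np.diag(self.b ** 2)
        return {
            "a": a, "f1": f1, "f0": f0, "Q": Q,
            "BBt": np.broadcast_to(BBt, (M, J, J)),
            "B": np.broadcast_to(np.diag(self.b), (M, J, J)),
            "mu0": np.exp(logmu0),
        }

    def check_age(self, t) -> None:
        lo, hi = self.age_range
        t = np.asarray(t, dtype=float)
        if np.any(t < lo) or np.any(t > hi):
            raise AgeRangeError(
                f"age {float(np.min(t)) if np.any(t < lo) else float(np.max(t))} "
                f"outside declared age range [{lo}, {hi}]")

    def hazard(self, t, y, x=None):
        """Quadratic hazard mu(t, y, x) for state vectors y (M, J)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        y = np.asarray(y, dtype=float).reshape(t.shape[0], self.dim)
        c = self.components(t, _tile_x(x, t.shape[0], len(self.covariates)))
        dev = y - c["f0"]
        return c["mu0"] + np.einsum("mi,mij,mj->m", dev, c["Q"], dev)

    def copy(self) -> "SPMParameters":
        return dataclasses.replace(self)

    def free_names(self) -> tuple[str, ...]:
        return _FIELDS


def _tile_x(x, M: int, p: int):
    if p == 0:
        return None
    x = np.asarray(x, dtype=float).reshape(-1)
    if x.size != p:
        raise ConfigurationError(f"expected {p} covariates, got {x.size}")
    return np.broadcast_to(x, (M, p))


def evaluate_components(params: SPMParameters, t: float, x=None) -> dict:
    """Point evaluation of every model component at age ``t``, covariates ``x``.

    Returns a dict with keys ``a`` (J x J), ``f1``, ``f0`` (J,), ``B`` (J x J),
    ``Q`` (J x J, symmetric NND) and ``mu0`` (scalar >= 0).
    Raises :class:`AgeRangeError` if ``t`` is outside the declared range.
    """
    params.check_age(t)
    c = params.components(np.array([t]), _tile_x(x, 1, len(params.covariates)))
    return {
        "a": c["a"][0], "f1": c["f1"][0], "f0": c["f0"][0],
        "B": c["B"][0], "Q": c["Q"][0], "mu0": float(c["mu0"][0]),
    }


# ----------------------------------------------------------------------
# validation
# ----------------------------------------------------------------------

def validate_model(params: SPMParameters, age_range=None, n_grid: int = 101,
                   x=None) -> list[tuple[str, str]]:
    """Check the model invariants on an age grid.

    Returns a list of ``(level, message)`` tuples with level ``"error"`` for
    invariant violations (Q not NND, gamma0 not PSD, non-finite entries) and
    ``"warning"`` for stability issues (an eigenvalue of a(t) with positive
    real part — positive feedback, trajectories diverge from f1).
    """
    issues: list[tuple[str, str]] = []
    lo, hi = age_range if age_range is not None else params.age_range
    grid = np.linspace(lo, hi, n_grid)
    X = _tile_x(x, n_grid, len(params.covariates))
    c = params.components(grid, X)
    if not np.allclose(params.Q0, params.Q0.T, atol=1e-12):
        issues.append(("error", "Q not symmetric"))
    else:
        w = np.linalg.eigvalsh(c["Q"])
        if np.min(w) < -1e-10:
            issues.append(("error",
                           f"Q not non-negative-definite (eigenvalue {np.min(w):.4g})"))
    g = params.gamma0
    if not np.allclose(g, g.T, atol=1e-12):
        issues.append(("error", "gamma0 not symmetric"))
    elif np.min(np.linalg.eigvalsh(g)) < -1e-10:
        issues.append(("error", "gamma0 not positive semi-definite"))
    if not np.all(np.isfinite(params.b)):
        issues.append(("error", "diffusion B has non-finite entries"))
    if np.any(params.b < 0):
        issues.append(("error", "diffusion diagonal must be >= 0"))
    if not np.all(np.isfinite(c["mu0"])):
        issues.append(("error", "baseline hazard mu0 non-finite on age grid"))
    eig_real = np.real(np.linalg.eigvals(c["a"]))
    if np.max(eig_real) > 0:
        t_bad = grid[int(np.argmax(np.max(eig_real.reshape(n_grid, -1), axis=1)))]
        issues.append(("warning",
                       f"feedback a(t) has an eigenvalue with positive real part "
                       f"(e.g. at age {t_bad:.1f}): dynamics diverge from f1"))
    return issues


def has_errors(issues: Sequence[tuple[str, str]]) -> bool:
    return any(level == "error" for level, _ in issues)


# ----------------------------------------------------------------------
# packing / unpacking on the unconstrained scale
# ----------------------------------------------------------------------

def _logchol_pack(mat: np.ndarray) -> np.ndarray:
    """Symmetric NND matrix -> lower Cholesky, log on the diagonal,
    row-major lower-triangle flattening."""
    J = mat.shape[0]
    try:
        L = np.linalg.cholesky(mat)
    except np.linalg.LinAlgError:
        L = np.linalg.cholesky(mat + 1e-10 * np.eye(J))
    out = []
    for i in range(J):
        for j in range(i + 1):
            out.append(np.log(max(L[i, i], 1e-154)) if i == j else L[i, j])
    return np.array(out)


def _logchol_unpack(v: np.ndarray, J: int) -> np.ndarray:
    L = np.zeros((J, J))
    k = 0
    for i in range(J):
        for j in range(i + 1):
            L[i, j] = np.exp(v[k]) if i == j else v[k]
            k += 1
    return L @ L.T


class ParameterCodec:
    """Bijective map between the free coefficients of an :class:`SPMParameters`
    template and a flat unconstrained real vector.

    Positive quantities (diffusion diagonal) go through log; symmetric NND
    matrices (Q0, gamma0) through a log-Cholesky factorisation; everything
    else is packed as-is.  Fields not listed in ``free`` are carried over
    from the template untouched.
    """

    def __init__(self, template: SPMParameters, free: Sequence[str] = DEFAULT_FREE):
        for name in free:
            if name not in _FIELDS:
                raise ConfigurationError(f"unknown parameter field {name!r}")
        self.template = template
        self.free = tuple(free)
        self._slices: dict[str, slice] = {}
        k = 0
        for name in self.free:
            size = self._packed(template, name).size
            self._slices[name] = slice(k, k + size)
            k += size
        self.n_free = k

    @staticmethod
    def _packed(params: SPMParameters, name: str) -> np.ndarray:
        val = getattr(params, name)
        tr = _TRANSFORM[name]
        if tr == "identity":
            return np.atleast_1d(np.asarray(val, dtype=float)).ravel().copy()
        if tr == "log":
            return np.log(np.maximum(np.atleast_1d(val), 1e-154))
        return _logchol_pack(np.asarray(val, dtype=float))

    def pack(self, params: SPMParameters) -> np.ndarray:
        return np.concatenate([self._packed(params, n) for n in self.free]) \
            if self.free else np.empty(0)

    def unpack(self, v: np.ndarray) -> SPMParameters:
        v = np.asarray(v, dtype=float)
        if v.shape != (self.n_free,):
            raise ConfigurationError(
                f"parameter vector length {v.size} != {self.n_free} free coefficients")
        out = self.template.copy()
        J = out.dim
        for name in self.free:
            chunk = v[self._slices[name]]
            tr = _TRANSFORM[name]
            ref = getattr(out, name)
            if tr == "identity":
                new = chunk.reshape(np.shape(ref)) if np.ndim(ref) else float(chunk[0])
            elif tr == "log":
                new = np.exp(chunk).reshape(np.shape(ref))
            else:
                new = _logchol_unpack(chunk, J)
            setattr(out, name, new)
        return out

    def names(self) -> list[str]:
        """Flat coordinate names, e.g. ``Q0[0]`` for multi-entry fields."""
        out = []
        for name in self.free:
            n = self._slices[name].stop - self._slices[name].start
            out.extend([name] if n == 1 else [f"{name}[{i}]" for i in range(n)])
        return out

    def constrained_values(self, v: np.ndarray) -> np.ndarray:
        """Free coefficients on the natural (constrained) scale, flattened in
        codec order — used for delta-method standard errors.  For NND matrix
        fields the natural coordinates are the lower-triangle entries of the
        matrix itself (so for a 1x1 Q0 this is Q0, not its Cholesky factor)."""
        p = self.unpack(v)
        out = []
        for n in self.free:
            val = getattr(p, n)
            if _TRANSFORM[n] == "logchol":
                m = np.asarray(val, dtype=float)
                out.append(np.array([m[i, j] for i in range(m.shape[0])
                                     for j in range(i + 1)]))
            else:
                out.append(np.atleast_1d(np.asarray(val, dtype=float)).ravel())
        return np.concatenate(out)

    def coordinate_kinds(self) -> list[str]:
        """Per-coordinate transform kind: 'identity', 'log', 'chol_diag' or
        'chol_off' — lets downstream code map Wald intervals through the
        monotone bijections coordinate-wise where that is exact."""
        kinds: list[str] = []
        J = self.template.dim
        for n in self.free:
            tr = _TRANSFORM[n]
            size = self._slices[n].stop - self._slices[n].start
            if tr == "logchol":
                for i in range(J):
                    for j in range(i + 1):
                        kinds.append("chol_diag" if i == j else "chol_off")
            else:
                kinds.extend([tr] * size)
        return kinds
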