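"""K-regime mixture containers shared by the latent-class and genetic models.

Both extensions attach a multinomial-logistic membership model on baseline
covariates X0,

    p_k = exp(b0_k + b1_k' x0) / (1 + sum_c exp(b0_c + b1_c' x0)),  k < K,
    p_K = 1 / (1 + sum_c exp(b0_c + b1_c' x0)),

(class K is the reference with linear predictor 0) to K regime-specific
parameter sets.  In the latent-class model the regime label is latent for
everyone; in the genetic model it is the observed genotype for a sub-sample.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .params import (SPMParameters, ParameterCodec, ConfigurationError,
                     _TRANSFORM, _FIELDS)

__all__ = ["MixtureModel", "LatentClassModel", "GeneticModel",
           "class_probabilities", "MixtureCodec", "ACTION_MODES"]

#: genetic-action loadings d_k on the unconstrained scale: regime-k value is
#: base + d_k * effect (regime 1 = major-allele homozygote reference).
ACTION_MODES = ("free", "dominant", "recessive", "additive", "shared")


def _action_loadings(mode: str, K: int) -> np.ndarray:
    if K == 2:
        return np.array([0.0, 1.0])
    if K != 3:
        raise ConfigurationError(f"action mode {mode!r} needs K=2 or K=3 regimes")
    return {"dominant": np.array([0.0, 1.0, 1.0]),
            "recessive": np.array([0.0, 0.0, 1.0]),
            "additive": np.array([0.0, 0.5, 1.0])}[mode]


@dataclass
class MixtureModel:
    """K regimes of :class:`SPMParameters` + multinomial-logistic membership."""

    components: list[SPMParameters]
    beta0: np.ndarray = field(default_factory=lambda: np.empty(0))
    beta1: np.ndarray | None = None
    membership_covariates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        K = len(self.components)
        if K < 1:
            raise ConfigurationError("mixture needs at least one regime")
        dims = {c.dim for c in self.components}
        if len(dims) != 1:
            raise ConfigurationError("all regimes must share the biomarker dimension")
        self.beta0 = np.asarray(self.beta0, dtype=float).reshape(-1)
        if self.beta0.size != K - 1:
            if self.beta0.size == 0:
                self.beta0 = np.zeros(K - 1)
            else:
                raise ConfigurationError(
                    f"beta0 must have K-1={K - 1} rows (class K is the reference)")
        p0 = len(self.membership_covariates)
        if self.beta1 is None:
            self.beta1 = np.zeros((K - 1, p0))
        self.beta1 = np.asarray(self.beta1, dtype=float).reshape(K - 1, p0)

    @property
    def K(self) -> int:
        return len(self.components)

    @property
    def dim(self) -> int:
        return self.components[0].dim

    def copy(self) -> "MixtureModel":
        out = dataclasses.replace(
            self, components=[c.copy() for c in self.components],
            beta0=self.beta0.copy(), beta1=self.beta1.copy())
        return out


class LatentClassModel(MixtureModel):
    """Mixture of SPM regimes with fully latent class membership."""


@dataclass
class GeneticModel(MixtureModel):
    """Mixture of SPM regimes indexed by a partially observed genotype.

    ``shared`` lists parameter fields constrained equal across genotypes;
    ``action`` optionally constrains one field to a dominant / recessive /
    additive pattern of the minor allele (applied on the unconstrained
    scale, so positivity-constrained components stay positive).
    """

    shared: tuple[str, ...] = ()
    action: tuple[str, str] | None = None   # (field, mode)

    def __post_init__(self) -> None:
        super().__post_init__()
        self.shared = tuple(self.shared)
        if self.action is not None:
            fld, mode = self.action
            if mode not in ("dominant", "recessive", "additive"):
                raise ConfigurationError(f"unknown action mode {mode!r}")
            if fld in self.shared:
                raise ConfigurationError(
                    f"component {fld!r} cannot be both shared and action-constrained")


def class_probabilities(model: MixtureModel, x0=None) -> np.ndarray:
    """Membership probabilities p(x0), reference class K last.

    ``x0`` may be a single covariate vector (returns shape (K,)) or a matrix
    of rows (returns (n, K)).  Probabilities are computed with a max-shifted
    softmax and sum to 1 exactly.
    """
    K = model.K
    p0 = model.beta1.shape[1]
    single = True
    if p0 == 0:
        eta = np.concatenate([model.beta0, [0.0]])[None, :]
    else:
        if x0 is None:
            raise ConfigurationError("membership model declares covariates but x0 is None")
        x0 = np.asarray(x0, dtype=float)
        single = x0.ndim == 1
        x0 = np.atleast_2d(x0)
        eta = np.concatenate(
            [model.beta0[None, :] + x0 @ model.beta1.T,
             np.zeros((x0.shape[0], 1))], axis=1)
    eta = eta - eta.max(axis=1, keepdims=True)
    e = np.exp(eta)
    p = e / e.sum(axis=1, keepdims=True)
    return p[0] if single and p.shape[0] == 1 else p


def sample_class(model_or_beta, x0=None, rng=None, beta1=None,
                 membership_covariates=()):
    """Draw a class label (1..K) from the multinomial-logistic membership
    model; returns ``(label, p)``.  Accepts either a MixtureModel or raw
    ``(beta0, beta1)`` coefficient arrays."""
    if isinstance(model_or_beta, MixtureModel):
        model = model_or_beta
    else:
        beta0 = np.asarray(model_or_beta, dtype=float).reshape(-1)
        K = beta0.size + 1
        model = MixtureModel(
            [SPMParameters() for _ in range(K)], beta0,
            beta1, membership_covariates)
    p = class_probabilities(model, x0)
    rng = np.random.default_rng() if rng is None else rng
    label = int(rng.choice(model.K, p=p)) + 1
    return label, p


# ----------------------------------------------------------------------
# flat unconstrained parameterisation of a mixture
# ----------------------------------------------------------------------

class MixtureCodec:
    """Codec for mixture models: membership coefficients plus regime
    parameters with per-field shared / per-regime / action-mode structure.

    ``free`` lists SPMParameters fields that are free; a field in ``shared``
    contributes one block (tied across regimes), the ``action`` field
    contributes a base block plus one effect block, any other free field
    contributes K per-regime blocks.  Membership coefficients (beta0, beta1)
    are free iff ``free_membership``.
    """

    def __init__(self, template: MixtureModel, free=(), shared=(),
                 free_membership: bool = True,
                 action: tuple[str, str] | None = None):
        if isinstance(template, GeneticModel):
            shared = tuple(shared) or template.shared
            action = action or template.action
        self.template = template
        self.free = tuple(free)
        self.shared = tuple(s for s in shared)
        self.action = action
        self.free_membership = free_membership
        if action is not None and action[0] in self.shared:
            raise ConfigurationError(
                f"component {action[0]!r} cannot be both shared and "
                "action-constrained")
        for name in self.free:
            if name not in _FIELDS:
                raise ConfigurationError(f"unknown parameter field {name!r}")
        K = template.K
        self._field_codecs = [
            {name: ParameterCodec(template.components[k], [name]) for name in self.free}
            for k in range(K)]
        self.n_membership = (template.beta0.size + template.beta1.size
                             if free_membership else 0)
        k = self.n_membership
        self._layout: list[tuple[str, str, slice]] = []
        for name in self.free:
            size = self._field_codecs[0][name].n_free
            if name in self.shared:
                self._layout.append((name, "shared", slice(k, k + size)))
                k += size
            elif action is not None and name == action[0]:
                self._layout.append((name, "action", slice(k, k + 2 * size)))
                k += 2 * size
            else:
                self._layout.append((name, "per", slice(k, k + K * size)))
                k += K * size
        self.n_free = k

    def pack(self, model: MixtureModel) -> np.ndarray:
        parts = []
        if self.free_membership:
            parts.append(model.beta0.ravel())
            parts.append(model.beta1.ravel())
        K = model.K
        for name, kind, _ in self._layout:
            packs = [self._field_codecs[k][name].pack(model.components[k])
                     for k in range(K)]
            if kind == "shared":
                parts.append(packs[0])
            elif kind == "action":
                parts.append(packs[0])
                parts.append(packs[-1] - packs[0])   # effect on unconstrained scale
            else:
                parts.extend(packs)
        return np.concatenate(parts) if parts else np.empty(0)

    def unpack(self, v: np.ndarray) -> MixtureModel:
        v = np.asarray(v, dtype=float)
        if v.shape != (self.n_free,):
            raise ConfigurationError(
                f"parameter vector length {v.size} != {self.n_free}")
        out = self.template.copy()
        K = out.K
        if self.free_membership:
            nb0 = out.beta0.size
            nb1 = out.beta1.size
            out.beta0 = v[:nb0].copy()
            out.beta1 = v[nb0:nb0 + nb1].reshape(out.beta1.shape)
        for name, kind, sl in self._layout:
            chunk = v[sl]
            size = self._field_codecs[0][name].n_free
            if kind == "shared":
                blocks = [chunk] * K
            elif kind == "action":
                base, eff = chunk[:size], chunk[size:]
                d = _action_loadings(self.action[1], K)
                blocks = [base + d[k] * eff for k in range(K)]
            else:
                blocks = [chunk[k * size:(k + 1) * size] for k in range(K)]
            for k in range(K):
                out.components[k] = _set_field(
                    self._field_codecs[k][name], out.components[k], blocks[k])
        return out

    def names(self) -> list[str]:
        out = []
        if self.free_membership:
            out += [f"beta0[{k + 1}]" for k in range(self.template.beta0.size)]
            out += [f"beta1[{k + 1},{j}]"
                    for k in range(self.template.beta1.shape[0])
                    for j in range(self.template.beta1.shape[1])]
        for name, kind, sl in self._layout:
            size = self._field_codecs[0][name].n_free
            sub = self._field_codecs[0][name].names()
            if kind == "shared":
                out += [f"{s}(shared)" for s in sub]
            elif kind == "action":
                out += [f"{s}(base)" for s in sub] + [f"{s}(effect)" for s in sub]
            else:
                out += [f"{s}(k={k + 1})" for k in range(self.template.K) for s in sub]
        return out

    def coordinate_kinds(self) -> list[str]:
        """Per-coordinate transform kind (see ParameterCodec): membership
        coefficients are unconstrained; action-effect blocks live on the
        unconstrained scale and are treated as identity coordinates."""
        kinds = ["identity"] * self.n_membership
        K = self.template.K
        for name, kind, _ in self._layout:
            sub = self._field_codecs[0][name].coordinate_kinds()
            if kind == "shared":
                kinds += sub
            elif kind == "action":
                kinds += sub + ["identity"] * len(sub)
            else:
                kinds += sub * K
        return kinds

    def constrained_values(self, v: np.ndarray) -> np.ndarray:
        """Natural-scale values in codec order: membership coefficients
        as-is, regime fields on their natural scale (shared fields once,
        action fields as base natural value + unconstrained effect)."""
        model = self.unpack(v)
        out = [v[:self.n_membership]]
        for name, kind, sl in self._layout:
            size = self._field_codecs[0][name].n_free
            chunk = v[sl]
            if kind == "shared":
                out.append(self._field_codecs[0][name].constrained_values(chunk))
            elif kind == "action":
                out.append(self._field_codecs[0][name]
                           .constrained_values(chunk[:size]))
                out.append(chunk[size:])
            else:
                for k in range(self.template.K):
                    out.append(ParameterCodec(model.components[k], [name])
                               .constrained_values(chunk[k * size:(k + 1) * size]))
        return np.concatenate(out) if out else np.empty(0)

    def effect_index(self) -> int:
        """Flat index of the (first coordinate of the) action-effect block —
        the genotype-effect parameter whose SE the power analyses track."""
        for name, kind, sl in self._layout:
            if kind == "action":
                size = self._field_codecs[0][name].n_free
                return sl.start + size
        raise ConfigurationError("codec has no action-constrained component")


def _set_field(codec: ParameterCodec, params: SPMParameters, block: np.ndarray):
    codec = ParameterCodec(params, codec.free)
    return codec.unpack(block)
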