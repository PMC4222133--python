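"""Latent-class SPM: finite mixture of SPM regimes with multinomial-logistic
class membership on baseline covariates.

The observed-data log-likelihood is the standard finite-mixture form

    sum_i log sum_k p_k(x0_i) exp(l_i^(k)),

with l_i^(k) the basic-SPM contribution of individual i under the class-k
parameters, computed with log-sum-exp stabilisation.  Posterior class
membership follows by Bayes' rule.  The mixture likelihood is maximised
directly (the M-step of EM would itself need numerical optimisation of
ODE-based likelihoods, so direct maximisation loses nothing); label
switching is resolved by canonically ordering classes by ascending f1
intercept.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

from .data import Cohort, Individual
from .estimation import (FitOptions, FitResult, UsageError, maximize,
                         uncertainty, _data_key)
from .likelihood import individual_logliks, prepare_cohort
from .mixture import (LatentClassModel, MixtureModel, MixtureCodec,
                      class_probabilities)
from .params import SPMParameters, ConfigurationError

__all__ = ["LatentClassModel", "class_probabilities", "component_logliks",
           "mixture_loglik", "posterior_class", "fit_latent", "select_K",
           "canonicalize", "DEFAULT_CLASS_FREE"]

#: default free fields per class when fitting a latent-class model: the
#: class-specific allostatic level and the hazard curvature, which is where
#: hidden heterogeneity in aging dynamics typically expresses itself.
DEFAULT_CLASS_FREE = ("f1_0", "Q0")


def _membership_x0(model: MixtureModel, cohort: Cohort):
    if not model.membership_covariates:
        return None
    idx = [cohort.covariate_names.index(c) for c in model.membership_covariates]
    return np.array([ind.x[idx] for ind in cohort], dtype=float)


def log_class_prior(model: MixtureModel, cohort: Cohort) -> np.ndarray:
    """log p_k(x0_i), shape (n, K)."""
    P = np.atleast_2d(class_probabilities(model, _membership_x0(model, cohort)))
    if P.shape[0] == 1:
        P = np.broadcast_to(P, (len(cohort), model.K))
    return np.log(np.maximum(P, 1e-300))


def component_logliks(model: MixtureModel, cohort: Cohort, prepared=None,
                      h_target: float = 0.25) -> np.ndarray:
    """Per-individual basic-SPM log-likelihoods under each regime, (n, K)."""
    if prepared is None:
        prepared = prepare_cohort(cohort, model.components[0])
    return np.column_stack([
        individual_logliks(comp, cohort, prepared, h_target=h_target)
        for comp in model.components])


def mixture_loglik(model: MixtureModel, cohort: Cohort, prepared=None,
                   h_target: float = 0.25) -> float:
    """Total latent-class mixture log-likelihood.

    Class labels are latent: any genotype codes present in the cohort are
    ignored here (the genetic model in :mod:`spmaging.genetic` is the one
    that conditions on observed labels)."""
    ll = component_logliks(model, cohort, prepared, h_target)
    return float(logsumexp(log_class_prior(model, cohort) + ll, axis=1).sum())


def posterior_class(model: MixtureModel, ind_or_cohort, prepared=None,
                    h_target: float = 0.25) -> np.ndarray:
    """Posterior membership probabilities, proportional to
    p_k(x0) exp(l^(k)); shape (K,) for an individual, (n, K) for a cohort."""
    single = isinstance(ind_or_cohort, Individual)
    cohort = Cohort([ind_or_cohort]) if single else ind_or_cohort
    if single:
        cohort.covariate_names = tuple(
            model.membership_covariates or model.components[0].covariates)
    lp = log_class_prior(model, cohort) + component_logliks(
        model, cohort, prepared, h_target)
    post = np.exp(lp - logsumexp(lp, axis=1, keepdims=True))
    return post[0] if single else post


def canonicalize(model: MixtureModel) -> MixtureModel:
    """Order classes by ascending f1 intercept (first biomarker) and re-express
    the membership coefficients in the permuted reference-class convention.
    Class probabilities are invariant under this relabelling."""
    order = np.argsort([c.f1_0[0] for c in model.components], kind="stable")
    out = model.copy()
    out.components = [model.components[k].copy() for k in order]
    eta0 = np.concatenate([model.beta0, [0.0]])
    eta1 = np.vstack([model.beta1, np.zeros((1, model.beta1.shape[1]))])
    out.beta0 = eta0[order][:-1] - eta0[order][-1]
    out.beta1 = eta1[order][:-1] - eta1[order][-1]
    return out


def _default_template(cohort: Cohort, K: int, base: SPMParameters) -> LatentClassModel:
    """K copies of ``base`` with f1 intercepts spread by +/- one empirical SD
    of the observed biomarker levels (start-value heuristic for K > 1)."""
    ys = np.concatenate([ind.obs_values[:, 0] for ind in cohort
                         if ind.obs_ages.size])
    sd = float(np.std(ys)) if ys.size else 1.0
    offsets = np.linspace(-sd, sd, K) if K > 1 else np.array([0.0])
    comps = []
    for k in range(K):
        c = base.copy()
        c.f1_0 = c.f1_0 + offsets[k]
        comps.append(c)
    return LatentClassModel(comps)


def fit_latent(cohort: Cohort, K: int, template=None,
               options: FitOptions | None = None,
               free=DEFAULT_CLASS_FREE, shared=(),
               free_membership: bool = True,
               h_target: float = 0.25) -> FitResult:
    """Maximise the latent-class mixture likelihood.

    ``template`` may be a :class:`LatentClassModel` (used as-is) or a basic
    :class:`SPMParameters` whose K spread copies seed the class-specific
    starts.  The returned fit is canonically ordered by f1 intercept; a
    fitted class prior below 1/(10 n) with no posterior mass is flagged in
    ``empty_classes``."""
    if K < 1:
        raise UsageError("K must be >= 1")
    options = options or FitOptions()
    if template is None:
        raise UsageError("a template (SPMParameters or LatentClassModel) is required")
    if isinstance(template, SPMParameters):
        template = _default_template(cohort, K, template)
    if template.K != K:
        raise UsageError(f"template has {template.K} classes, expected {K}")
    if K == 1:
        free_membership = False
    codec = MixtureCodec(template, free=free, shared=shared,
                         free_membership=free_membership)
    prep = prepare_cohort(cohort, template.components[0])

    def ll(u):
        return mixture_loglik(codec.unpack(u), cohort, prep, h_target)

    u0 = codec.pack(template)
    u_best, records = maximize(ll, u0, options, codec.coordinate_kinds())
    cov_u, se_u, bse, values, pd = uncertainty(ll, codec, u_best,
                                               options.hessian_step)
    best_ll = ll(u_best)
    fitted = canonicalize(codec.unpack(u_best))
    result = FitResult(
        params=fitted, codec=codec, u=u_best, loglik=best_ll,
        k=codec.n_free, n=len(cohort), starts=records,
        converged=any(r.converged and abs(r.loglik - best_ll) < 1e-6
                      for r in records),
        cov_u=cov_u, se_u=se_u, bse=bse, values=values,
        names=codec.names(), kinds=codec.coordinate_kinds(), hessian_pd=pd,
        seed=options.seed, data_key=_data_key(cohort))
    # empty-class degeneracy flag
    prior = np.exp(log_class_prior(fitted, cohort)).mean(axis=0)
    post = posterior_class(fitted, cohort, prep, h_target)
    result.empty_classes = [int(k + 1) for k in range(K)
                            if prior[k] < 1.0 / (10 * len(cohort))
                            and post[:, k].max() < 0.5]
    return result


def select_K(cohort: Cohort, K_list, template, options=None,
             free=DEFAULT_CLASS_FREE, shared=(), h_target: float = 0.25):
    """Fit the latent-class model for each K and tabulate logL / AIC / BIC.

    Returns ``(table, fits)``; the table flags the lowest-BIC K as the
    recommendation but never auto-selects.  A likelihood-ratio test across
    different K is deliberately not offered (the null lies on the boundary
    of the parameter space, so the chi-square reference is invalid)."""
    import pandas as pd
    if not len(list(K_list)):
        raise UsageError("K_list must be non-empty")
    rows, fits = [], {}
    for K in K_list:
        f = fit_latent(cohort, K, template, options, free, shared,
                       h_target=h_target)
        fits[K] = f
        rows.append({"K": K, "k_params": f.k, "loglik": f.loglik,
                     "aic": f.aic, "bic": f.bic})
    tab = pd.DataFrame(rows)
    tab["recommended"] = tab["bic"] == tab["bic"].min()
    return tab, fits
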