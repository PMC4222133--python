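"""Genetic SPM: joint likelihood for genotyped and non-genotyped individuals.

The genotype (or any discrete, partially observed baseline covariate) indexes
K regime-specific SPM parameter sets, with genotype frequencies given by the
same multinomial-logistic model as the latent classes.  Genotyped individuals
contribute

    log p_{k_i}(x0_i) + l_i^(k_i),

non-genotyped individuals the mixture term log sum_k p_k(x0_i) exp(l_i^(k)).
Both parts share parameters — adding the non-genotyped sub-sample therefore
adds information about the regime parameters, which is the source of the
power gain over genotyped-only analyses.  Genotype missingness is assumed
independent of outcomes given the baseline covariates (missing at random).

Genetic action on a component is expressed on the unconstrained scale:
regime-k value = base + d_k * effect with loadings d = (0, 1, 1) dominant,
(0, 0, 1) recessive, (0, 1/2, 1) additive for a biallelic genotype
(K = 3; K = 2 is carrier/non-carrier), keeping positivity-constrained
components positive under any effect size.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.special import logsumexp

from .data import Cohort, DataError
from .estimation import (FitOptions, FitResult, UsageError, lr_test,
                         maximize, uncertainty, _data_key)
from .latent import component_logliks, log_class_prior
from .likelihood import prepare_cohort
from .mixture import GeneticModel, MixtureCodec
from .params import ConfigurationError

__all__ = ["GeneticModel", "genetic_loglik", "fit_genetic",
           "test_genetic_effect"]


def _labels(cohort: Cohort, K: int) -> np.ndarray:
    lab = np.array([-1 if ind.genotype is None else int(ind.genotype)
                    for ind in cohort])
    bad = (lab != -1) & ((lab < 1) | (lab > K))
    if bad.any():
        ids = [cohort.individuals[i].id for i in np.flatnonzero(bad)[:5]]
        raise DataError(f"genotype labels outside 1..{K} for ids {ids}")
    return lab


def genetic_loglik(model: GeneticModel, cohort: Cohort, prepared=None,
                   h_target: float = 0.25) -> float:
    """Joint log-likelihood over genotyped and non-genotyped individuals.

    With no genotyped individuals this is exactly the latent-class mixture
    likelihood; with everyone genotyped it is the complete-data likelihood
    (regime terms plus multinomial genotype-probability terms)."""
    lab = _labels(cohort, model.K)
    ll = component_logliks(model, cohort, prepared, h_target)
    lp = log_class_prior(model, cohort)
    obs = lab > 0
    total = 0.0
    if obs.any():
        idx = lab[obs] - 1
        rows = np.flatnonzero(obs)
        total += float((lp[rows, idx] + ll[rows, idx]).sum())
    if (~obs).any():
        total += float(logsumexp(lp[~obs] + ll[~obs], axis=1).sum())
    return total


def fit_genetic(cohort: Cohort, template: GeneticModel,
                options: FitOptions | None = None,
                free=("Q0",), free_membership: bool = True,
                h_target: float = 0.25) -> FitResult:
    """Maximise the genetic-SPM likelihood.

    The constraint map comes from the template: fields in
    ``template.shared`` are tied across genotypes and ``template.action``
    applies a dominant/recessive/additive pattern to one component.  With
    zero genotyped individuals the model degenerates to the latent-class
    SPM (a warning is issued)."""
    if len(cohort) == 0:
        raise UsageError("empty cohort")
    options = options or FitOptions()
    lab = _labels(cohort, template.K)
    if not (lab > 0).any():
        warnings.warn("no genotyped individuals: the genetic model reduces to "
                      "the latent-class mixture", RuntimeWarning)
    codec = MixtureCodec(template, free=free, free_membership=free_membership)
    prep = prepare_cohort(cohort, template.components[0])

    def ll(u):
        return genetic_loglik(codec.unpack(u), cohort, prep, h_target)

    u0 = codec.pack(template)
    u_best, records = maximize(ll, u0, options, codec.coordinate_kinds())
    cov_u, se_u, bse, values, pd = uncertainty(ll, codec, u_best,
                                               options.hessian_step)
    best_ll = ll(u_best)
    return FitResult(
        params=codec.unpack(u_best), codec=codec, u=u_best, loglik=best_ll,
        k=codec.n_free, n=len(cohort), starts=records,
        converged=any(r.converged and abs(r.loglik - best_ll) < 1e-6
                      for r in records),
        cov_u=cov_u, se_u=se_u, bse=bse, values=values,
        names=codec.names(), kinds=codec.coordinate_kinds(), hessian_pd=pd,
        seed=options.seed, data_key=_data_key(cohort))


def test_genetic_effect(cohort: Cohort, template: GeneticModel,
                        component: str = "Q0",
                        modes=("shared", "additive", "free"),
                        options: FitOptions | None = None,
                        free_membership: bool = True,
                        h_target: float = 0.25):
    """Fit a sequence of genetic-action hypotheses on one component and
    compare them.

    ``modes`` are fitted in order; nested pairs (shared within dominant /
    recessive / additive / free; dominant, recessive and additive within
    free) get likelihood-ratio p-values, every pair is comparable by AIC.
    Trying several action modes is recommended practice — the form of
    genetic action is not known a priori.  Returns ``(table, fits)``."""
    import pandas as pd
    if component not in template.components[0].free_names():
        raise ConfigurationError(f"unknown component {component!r}")
    options = options or FitOptions()
    fits: dict[str, FitResult] = {}
    for mode in modes:
        t = template.copy()
        if mode == "shared":
            t.shared = tuple(set(template.shared) | {component})
            t.action = None
        elif mode == "free":
            t.shared = tuple(s for s in template.shared if s != component)
            t.action = None
        elif mode in ("dominant", "recessive", "additive"):
            t.shared = tuple(s for s in template.shared if s != component)
            t.action = (component, mode)
        else:
            raise ConfigurationError(f"unknown action mode {mode!r}")
        fits[mode] = fit_genetic(cohort, t, options, free=(component,),
                                 free_membership=free_membership,
                                 h_target=h_target)
    rows = [{"mode": m, "k": f.k, "loglik": f.loglik, "aic": f.aic}
            for m, f in fits.items()]
    tab = pd.DataFrame(rows)
    nested = {("shared", "dominant"), ("shared", "recessive"),
              ("shared", "additive"), ("shared", "free"),
              ("dominant", "free"), ("recessive", "free"),
              ("additive", "free")}
    lrt_rows = []
    for (m0, m1) in nested:
        if m0 in fits and m1 in fits:
            stat = max(0.0, 2 * (fits[m1].loglik - fits[m0].loglik))
            df = fits[m1].k - fits[m0].k
            if df >= 1:
                from scipy import stats as _st
                lrt_rows.append({"null": m0, "alt": m1, "stat": stat,
                                 "df": df, "p": float(_st.chi2.sf(stat, df))})
    return tab, pd.DataFrame(lrt_rows), fits
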