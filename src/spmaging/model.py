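"""Model / Results front-end in the style of statsmodels.

Three model classes wrap the functional layer: :class:`SPM` (basic model),
:class:`LatentClassSPM` and :class:`GeneticSPM`.  A model is built from a
cohort (or the two data frames) plus a parameter template with free/fixed
structure; ``fit()`` returns a results object carrying the estimates, their
uncertainty, model-comparison statistics and a ``summary()`` table, with
simulation, prediction and forecasting hanging off the fitted objects.

    >>> model = SPM(cohort, template, free=("a0", "Q0", "mu0_c0"))
    >>> res = model.fit()
    >>> print(res.summary())
    >>> res.predict_individual(cohort.individuals[0], horizon=100)
"""

from __future__ import annotations

import numpy as np

from . import estimation, genetic, latent, likelihood, predict
from .data import Cohort, cohort_from_frames
from .estimation import FitOptions, FitResult, UsageError
from .mixture import GeneticModel, LatentClassModel, MixtureModel
from .params import DEFAULT_FREE, SPMParameters, validate_model

__all__ = ["SPM", "LatentClassSPM", "GeneticSPM", "SPMResults",
           "LatentClassResults", "GeneticResults"]


def _summary_table(fit: FitResult, title: str = "SPM maximum likelihood"):
    from statsmodels.iolib.table import SimpleTable
    ci = fit.conf_int()
    rows = [[name, f"{v:.6g}", f"{se:.3g}", f"{lo:.6g}", f"{hi:.6g}"]
            for name, v, se, (lo, hi) in zip(fit.names, fit.values,
                                             fit.bse, ci)]
    header = ["parameter", "estimate", "std err", "[0.025", "0.975]"]
    tab = SimpleTable(rows, header, title=title)
    extra = SimpleTable(
        [["n individuals", str(fit.n)],
         ["free parameters", str(fit.k)],
         ["log-likelihood", f"{fit.loglik:.4f}"],
         ["AIC", f"{fit.aic:.4f}"],
         ["BIC", f"{fit.bic:.4f}"],
         ["converged", str(fit.converged)],
         ["Hessian PD", str(fit.hessian_pd)]])
    return str(tab) + "\n" + str(extra)


class _ModelBase:
    def __init__(self, cohort):
        if isinstance(cohort, tuple):
            cohort = cohort_from_frames(*cohort)
        if not isinstance(cohort, Cohort):
            raise UsageError("expected a Cohort or (long_df, surv_df) tuple")
        self.cohort = cohort

    @classmethod
    def from_frames(cls, long_df, surv_df, *args, **kwargs):
        return cls(cohort_from_frames(long_df, surv_df), *args, **kwargs)


class SPM(_ModelBase):
    """Basic stochastic process model of aging, built from a cohort and a
    parameter template whose ``free`` fields are estimated."""

    def __init__(self, cohort, template: SPMParameters,
                 free=DEFAULT_FREE, h_target: float = 0.25):
        super().__init__(cohort)
        self.template = template
        self.free = tuple(free)
        self.h_target = h_target
        self._prepared = likelihood.prepare_cohort(self.cohort, template)

    def loglike(self, params: SPMParameters | None = None) -> float:
        return likelihood.cohort_loglik(params or self.template, self.cohort,
                                        self._prepared, h_target=self.h_target)

    def validate(self):
        return validate_model(self.template)

    def fit(self, options: FitOptions | None = None, **kw) -> "SPMResults":
        if kw:
            options = FitOptions(**{**(options.__dict__ if options else {}), **kw})
        res = estimation.fit(self.cohort, self.template, self.free,
                             options, h_target=self.h_target)
        return SPMResults(self, res)


class LatentClassSPM(_ModelBase):
    """Latent-class SPM with K regimes and logistic class membership."""

    def __init__(self, cohort, K: int, template,
                 free=latent.DEFAULT_CLASS_FREE, shared=(),
                 free_membership: bool = True, h_target: float = 0.25):
        super().__init__(cohort)
        self.K = int(K)
        self.template = template
        self.free = tuple(free)
        self.shared = tuple(shared)
        self.free_membership = free_membership
        self.h_target = h_target

    def loglike(self, model: MixtureModel) -> float:
        return latent.mixture_loglik(model, self.cohort, h_target=self.h_target)

    def fit(self, options: FitOptions | None = None) -> "LatentClassResults":
        res = latent.fit_latent(self.cohort, self.K, self.template, options,
                                self.free, self.shared, self.free_membership,
                                h_target=self.h_target)
        return LatentClassResults(self, res)

    def select_K(self, K_list, options=None):
        return latent.select_K(self.cohort, K_list, self.template, options,
                               self.free, self.shared, h_target=self.h_target)


class GeneticSPM(_ModelBase):
    """Genetic SPM: regimes indexed by a partially observed genotype."""

    def __init__(self, cohort, template: GeneticModel, free=("Q0",),
                 free_membership: bool = True, h_target: float = 0.25):
        super().__init__(cohort)
        self.template = template
        self.free = tuple(free)
        self.free_membership = free_membership
        self.h_target = h_target

    def loglike(self, model: GeneticModel) -> float:
        return genetic.genetic_loglik(model, self.cohort, h_target=self.h_target)

    def fit(self, options: FitOptions | None = None) -> "GeneticResults":
        res = genetic.fit_genetic(self.cohort, self.template, options,
                                  self.free, self.free_membership,
                                  h_target=self.h_target)
        return GeneticResults(self, res)

    def test_effect(self, component="Q0", modes=("shared", "additive", "free"),
                    options=None):
        return genetic.test_genetic_effect(
            self.cohort, self.template, component, modes, options,
            self.free_membership, h_target=self.h_target)


class _ResultsBase:
    def __init__(self, model, fitres: FitResult):
        self.model = model
        self._fit = fitres

    # statsmodels-flavoured accessors
    @property
    def params(self):
        return self._fit.params

    @property
    def llf(self) -> float:
        return self._fit.loglik

    @property
    def aic(self) -> float:
        return self._fit.aic

    @property
    def bic(self) -> float:
        return self._fit.bic

    @property
    def bse(self) -> np.ndarray:
        return self._fit.bse

    @property
    def converged(self) -> bool:
        return self._fit.converged

    def conf_int(self, alpha: float = 0.05):
        return self._fit.conf_int(alpha)

    def lr_test(self, other: "_ResultsBase"):
        """LRT of ``other`` (null, nested) against this fit (alternative)."""
        return estimation.lr_test(other._fit, self._fit)

    @property
    def fit_result(self) -> FitResult:
        return self._fit

    def summary(self) -> str:
        return _summary_table(self._fit, title=type(self).__name__)


class SPMResults(_ResultsBase):
    def predict_individual(self, ind, s=None, horizon=None, grid=None):
        return predict.predict_individual(self.params, ind, s=s,
                                          horizon=horizon, grid=grid)

    def marginal_survival(self, x=None, t0=None, horizon=None, grid=None):
        return likelihood.marginal_survival(self.params, x=x, t0=t0,
                                            horizon=horizon, grid=grid)

    def forecast(self, entry_age, horizon, n_sim=10000, scenario=None,
                 seed=0, **kw):
        return predict.forecast_population(self.params, entry_age, horizon,
                                           n_sim, scenario, seed, **kw)

    def simulate(self, n, scheme, rng=None, **kw):
        from .simulate import simulate_cohort
        return simulate_cohort(self.params, n, scheme, rng=rng, **kw)


class LatentClassResults(_ResultsBase):
    @property
    def empty_classes(self):
        return getattr(self._fit, "empty_classes", [])

    def posterior(self):
        """Posterior membership table (n, K)."""
        return latent.posterior_class(self.params, self.model.cohort)

    def classify(self):
        """Modal posterior class per individual (1..K)."""
        return 1 + np.argmax(self.posterior(), axis=1)

    def predict_individual(self, ind, s=None, horizon=None, grid=None):
        return predict.predict_latent(self.params, ind, s=s, horizon=horizon,
                                      grid=grid)


class GeneticResults(_ResultsBase):
    def effect_se(self):
        """Unconstrained-scale SE of the genetic-action effect parameter."""
        idx = self._fit.codec.effect_index()
        return float(self._fit.se_u[idx])

    def predict_individual(self, ind, s=None, horizon=None, grid=None):
        return predict.predict_latent(self.params, ind, s=s, horizon=horizon,
                                      grid=grid)

    def forecast(self, entry_age, horizon, n_sim=10000, scenario=None,
                 seed=0, **kw):
        return predict.forecast_population(self.params, entry_age, horizon,
                                           n_sim, scenario, seed, **kw)
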