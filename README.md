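# spmaging

Stochastic process models of aging: joint maximum-likelihood analysis of
longitudinal biomarker trajectories and survival, built for biodemographic
and epidemiological studies in which repeated physiological measurements
(blood pressure, glucose, BMI, …) are collected at examinations and
follow-up ends in death or censoring.

## The model

A J-vector of biomarkers Y<sub>t</sub> follows a mean-reverting diffusion
(homeostatic regulation), and the event hazard is a quadratic, U-shaped
function of the deviation from an age-dependent physiological norm:

    dY_t = a(t, X) (Y_t − f1(t, X)) dt + B(t, X) dW_t
    μ(t, Y_t, X) = μ0(t, X) + (Y_t − f0(t, X))ᵀ Q(t, X) (Y_t − f0(t, X))

The estimable components map onto aging mechanisms: adaptive capacity
`a`, allostatic trajectory `f1`, physiological norm `f0` (f1 − f0 =
allostatic load), stress resistance via the hazard curvature `Q(t)`, and a
Gompertz baseline `μ0`. The likelihood propagates the conditional-Gaussian
moments m(t), γ(t) of the latent state between examinations,

    dm/dt = a(m − f1) − 2γQ(m − f0),   dγ/dt = aγ + γaᵀ + BBᵀ − 2γQγ,

and combines one-step-ahead Gaussian densities with the survival factor
exp(−∫μ̄ dt), μ̄ = μ0 + (m−f0)ᵀQ(m−f0) + tr(Qγ).

Beyond the basic model the package provides:

* a **latent-class** extension — a finite mixture of regimes with
  multinomial-logistic membership, for hidden population heterogeneity,
  with posterior classification and AIC/BIC selection of K;
* a **genetic** extension — regimes indexed by a genotype observed only
  for a sub-sample; genotyped and non-genotyped parts of the likelihood
  share parameters, so the non-genotyped majority adds power; dominant /
  recessive / additive action hypotheses are testable by LRT and AIC;
* **dynamic individual prediction** (conditional survival and expected
  trajectory, updatable with each new measurement) and **microsimulation
  forecasting** with "what-if" component interventions under common
  random numbers;
* a cohort **simulator** (Euler–Maruyama trajectories, stepwise event
  generation, examination schemes, partial genotyping) that doubles as a
  Monte-Carlo oracle for the likelihood machinery;
* both continuous-time (moment-ODE) and discrete-time likelihood
  variants.

## Worked example

```python
import numpy as np
from spmaging import SPM, FitOptions, ScenarioSpec, Modification, forecast_population
from spmaging.presets import study_params, study_scheme
from spmaging.simulate import simulate_cohort

truth = study_params()                       # reference scalar model, see docs/methods.md
cohort = simulate_cohort(truth, 500, study_scheme(), rng=42)

model = SPM(cohort, study_params(a0=-0.2, Q0=1e-4),
            free=("a0", "Q0", "mu0_c0", "mu0_theta"))
res = model.fit(FitOptions(starts=2, seed=0))
print(res.summary())
```

```
                      SPMResults
=====================================================
parameter   estimate  std err    [0.025      0.975]
-----------------------------------------------------
       a0   -0.301446 0.00644   -0.314071   -0.288822
       Q0 3.25757e-05 1.6e-05 1.24597e-05 8.51684e-05
   mu0_c0    -10.9072   0.621    -12.1235    -9.69095
mu0_theta   0.0912236 0.00678    0.077944    0.104503
-----------------------------------------------------
  n individuals         500
free parameters           4
 log-likelihood -20129.3373
            AIC  40266.6747
            BIC  40283.5331
      converged        True
     Hessian PD        True
```

The adaptive capacity is recovered at −0.30 (truth −0.3): disturbances
decay with a ~3-year relaxation time. The Gompertz slope 0.091/y (truth
0.085) is a mortality-rate doubling time of ~8 years, and the curvature
estimate 3.3e-5 (truth 2e-5, inside the interval) quantifies how strongly
deviations from the physiological norm raise mortality.

```python
pr = res.predict_individual(cohort.individuals[0], horizon=95.0)
print(f"S(95 | {pr.s:.0f}) = {pr.survival[-1]:.3f}")
# S(95 | 40) = 0.270

sc = ScenarioSpec("stress_resist", [Modification("Q", "scale", 0.5)])
tab = forecast_population(res.params, 40.0, 95.0, n_sim=20000, scenario=sc, seed=1)
row = tab.iloc[(tab.age - 85).abs().idxmin()]
print(f"S(85) baseline {row['survival_base']:.3f} vs scenario {row['survival_stress_resist']:.3f}")
# S(85) baseline 0.596 vs scenario 0.625
```

Halving the hazard curvature (a stress-resistance intervention) lifts
survival to 85 by three percentage points in this fitted population; the
two arms share random numbers, so the contrast is paired.

Latent-class and genetic analyses follow the same pattern through
`LatentClassSPM` and `GeneticSPM` (or the functional layer
`fit_latent` / `select_K` / `fit_genetic` / `test_genetic_effect`).

A CLI mirrors the library for shell pipelines:

```bash
spmaging simulate --config config.yaml --seed 1 --out data/
spmaging fit --data data/ --config config.yaml --out fit.json
spmaging fit-latent --data data/ --config config.yaml -K 2
spmaging fit-genetic --data data/ --config config.yaml --mode additive --component Q0
spmaging predict --data data/ --config config.yaml --id 0 --horizon 95
spmaging forecast --config config.yaml --scenario scenario.yaml --n 10000
spmaging validate --config config.yaml
```

Data are two delimited-text tables (long-format examinations `id, age,
y1..yJ`; one-row-per-individual survival `id, t0, tau, delta,
covariates…, genotype` with blank genotype = not genotyped); the config
schema is documented in `spmaging/config.py`.

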