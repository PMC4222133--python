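# Methods

## The model

`spmaging` implements a joint model for longitudinal biomarker trajectories
and a terminal time-to-event outcome in which the biomarker vector
Y<sub>t</sub> (t = age in years, dimension J) follows a mean-reverting
diffusion

    dY_t = a(t, X) (Y_t − f1(t, X)) dt + B(t, X) dW_t,

and the event hazard is a quadratic (U-shaped) function of the deviation of
Y<sub>t</sub> from an age-dependent norm:

    μ(t, Y_t, X) = μ0(t, X) + (Y_t − f0(t, X))ᵀ Q(t, X) (Y_t − f0(t, X)).

The components carry direct aging interpretations: `a` (negative-feedback
matrix) is the adaptive capacity — how fast the organism returns to its
allostatic trajectory `f1` after a disturbance; `f0` is the physiological
norm that minimises risk at each age; the gap f1 − f0 measures allostatic
load; `Q` is the hazard curvature, inversely related to stress resistance
(its growth with age models declining stress resistance); `μ0` is the
baseline (Gompertz) mortality at the norm; `B` scales exogenous Wiener
noise; X are time-independent baseline covariates.

Two mixture extensions share a multinomial-logistic membership model on
baseline covariates X⁰ (reference class K has linear predictor 0):

* **Latent-class model** — K regimes with fully latent membership; the
  observed-data likelihood is the finite-mixture form
  Σ<sub>i</sub> log Σ<sub>k</sub> p<sub>k</sub>(x⁰<sub>i</sub>)
  exp(ℓ<sub>i</sub><sup>(k)</sup>), evaluated with log-sum-exp.
* **Genetic model** — the regime label is an observed genotype for a
  sub-sample and latent for the rest. Genotyped individuals contribute
  log p<sub>k<sub>i</sub></sub> + ℓ<sub>i</sub><sup>(k<sub>i</sub>)</sup>,
  the rest the mixture term; both parts share parameters, which is what
  makes non-genotyped individuals informative about genotype effects.
  Genotype missingness is assumed independent of outcomes given X⁰
  (missing at random) — an assumption, not something the data can check
  here.

### Parametric forms

The functional forms of the components are not dictated by the theory; the
defaults are the simplest identifiable choices, each replaceable by editing
the parameter object or wrapping component evaluation (the scenario
machinery uses exactly that hook):

| component | default form | constraint |
|---|---|---|
| a(t) | a0 + a1·t | stability *warning* if an eigenvalue has positive real part |
| f1(t,x) | f1₀ + f1₁·t + F₁x | — |
| f0(t,x) | f0₀ + f0₁·t + F₀x | — |
| B | constant diagonal b | b ≥ 0 (log-parameterised) |
| Q(t) | Q0·max(1 + q1·t, 0) | Q0 symmetric NND (log-Cholesky) |
| μ0(t,x) | exp(c0 + θ·t + gᵀx) | positive by construction |

Covariates shift the f1/f0 intercepts additively and μ0 multiplicatively;
a, B and Q are covariate-free by default (regime-specific versions of them
are available through the mixture models). Model validation evaluates the
invariants on a grid of 101 ages over the declared age range.

## Likelihood

Between examinations the conditional law of Y<sub>t</sub> given survival
and the observation history is approximated as Gaussian with moments m(t),
γ(t) solving

    dm/dt = a (m − f1) − 2 γ Q (m − f0)
    dγ/dt = a γ + γ aᵀ + B Bᵀ − 2 γ Q γ,

with mean hazard μ̄ = μ0 + (m−f0)ᵀQ(m−f0) + tr(Qγ). With Q = 0 these are
the exact unconditional OU moments. An individual's contribution is

    Σ_j log N(y_{j+1}; m(t_{j+1}⁻), γ(t_{j+1}⁻)) − ∫_{t0}^{τ} μ̄ dt
        + δ·log μ̄(τ⁻).

Biomarkers are treated as observed exactly (no measurement-error term in
the SDE): the state resets to (m = y, γ = 0) at each examination.
Conventions: an examination at the entry age is conditioned on (it resets
the state but contributes no density term); for an individual censored at
their last examination the survival integral simply ends at τ with no
density term there; with delayed entry, integration starts at the
individual entry age from the initial law (m0, γ0). With an optional
measurement-error SD σ > 0, the hard reset is replaced by the standard
linear-Gaussian filter update (gain γ(γ + σ²I)⁻¹) and the density terms use
γ + σ²I; this mode is sequential per individual and intended for small
analyses.

### Numerics

Exact observation makes all inter-observation segments conditionally
independent, so the default solver propagates every segment of the whole
cohort at once: a classical RK4 scheme on (m, γ, ∫μ̄) with step ≤ 0.25 y
(for the scalar model a compiled per-segment kernel; for J > 1 a vectorised
batch path with segments grouped by power-of-two step counts). An adaptive
RK45 path (rtol 1e-8, atol 1e-10) is the accuracy reference and the engine
for marginal survival, moment propagation and prediction (rtol 1e-10
there). The fixed-step default agrees with the adaptive reference to
~1e-5 in individual log-likelihood terms and ~1e-8 in relative cohort
log-likelihood — far below Monte-Carlo noise at the cohort sizes used,
while making the replicated experiments below feasible. γ is clipped at 0
(scalar) or to its PSD cone (matrix case, with a warning below −1e-10);
log arguments are floored at 1e-300.

The discrete-time likelihood variant uses Gaussian transition factors
N(y_{j+1}; y_j + a(t_j)(y_j − f1(t_j))Δ, BBᵀΔ) between consecutive
observations, survival factors exp(−μ(t_j, y_j)Δ) with the observed state,
and event factor 1 − exp(−μΔ) at the final step; observation ages must lie
on the step grid (tolerance 1e-6) or be binned explicitly. On densely
observed data (Δ = 0.05 y) it agrees with the continuous-time
log-likelihood to < 0.5% relative.

## Estimation

Free coefficients are optimised on an unconstrained scale (log for the
diffusion diagonal, log-Cholesky for NND matrices, multinomial-logit
reference-class coding for membership). The default optimiser is BFGS with
finite-difference gradients, multi-start (template values plus seeded
perturbations by factors U[0.5, 2] on the log scale), with a Nelder-Mead
polish only when BFGS ends with a non-trivial gradient. Standard errors
come from the inverse central-difference Hessian (step 1e-4) on the
unconstrained scale, delta-method mapped to the natural scale; Wald
intervals map the unconstrained endpoints through the bijection where that
is monotone (log coordinates; 1×1 curvature matrices). Ties across starts
go to the highest log-likelihood, then fewest iterations. Nested models
are compared by the likelihood-ratio test, non-nested ones by AIC; BIC is
reported alongside for mixture-order selection, and the API refuses an LRT
across different K (boundary non-regularity).

The latent-class likelihood is maximised directly rather than by EM: with
ODE-based component likelihoods the M-step would itself be a numerical
optimisation, so EM would save nothing. Label switching is resolved by
ordering classes by ascending f1 intercept; the membership coefficients
are re-expressed in the permuted reference-class coding (class
probabilities are invariant). Genetic action modes constrain the regime
values of one component on the unconstrained scale — regime k gets
base + d_k·effect with d = (0,1,1) dominant, (0,0,1) recessive,
(0,½,1) additive — which keeps positivity automatically and makes the
additive heterozygote the geometric midpoint on the natural scale.

The f0-versus-μ0 trade-off (a shifted norm can partly masquerade as a
higher baseline) is a known soft-identifiability direction; fits report
the full parameter covariance so high correlations are visible, and the
reference experiments keep f0 fixed when all 8 scalar-model parameters
are free.

## Simulation

Trajectories use Euler–Maruyama with dt = 0.05 y (configurable); events
are drawn stepwise with probability 1 − exp(−μ(t_k + dt/2, y_k)·dt) and
the event age recorded at the step midpoint. Evaluating the hazard's age
argument at the midpoint (the state stays y_k) cancels the leading O(dt)
survival bias for age-increasing hazards: against the Gompertz closed form
the simulated survival is unbiased to the Monte-Carlo resolution of 60
independent 100k-path runs, where start-of-step evaluation leaves a
detectable ~3-SE deficit. Draws are consumed
every step for every individual regardless of vital status, so runs with
the same seed are path-wise paired across parameter changes — this is the
common-random-numbers mechanism the forecasting arms rely on. Examination
schedules support per-visit jitter, random missingness and optional
Gaussian measurement noise (off by default, matching the exact-observation
likelihood). Mixture cohorts draw the regime per individual from the
membership model and retain the label as an observed genotype with the
requested probability. Simulated cohorts store the generating model and
true labels for recovery experiments.

## Prediction and forecasting

Individual prediction initialises the moment state at the last observation
at or before the conditioning age s, propagates the moment ODEs, and
reports S(u|s) = exp(−∫ₛᵘ μ̄) with the conditional mean trajectory and a
Gaussian band m ± z√γ (an approximation — the true conditional law is only
approximately Gaussian). Re-running after a new measurement is the dynamic
update; the survival curve satisfies the tower identity
S(u|s) = S(s′|s)·S(u|s′) to solver precision. Mixture predictions weight
regime-specific curves by the posterior membership given the history and
survival to s (degenerate at an observed genotype).

Population forecasts aggregate simulated life histories (default
n_sim = 10,000) on an age grid: survival fraction with binomial SE, mean
biomarker among survivors, cumulative deaths, and median lifetime per arm.
"What-if" scenarios scale or shift any component from a start age; the
modified model is validated (Q must stay NND, μ0 non-negative) before use.
Baseline and scenario arms share one seeded stream by default, so a null
scenario reproduces the baseline columns exactly and contrasts are paired.
Population heterogeneity enters only through declared covariate/genotype
distributions and the initial law — no migration or fertility dynamics.

## Reference study conditions

Simulation experiments use a single scalar biomarker followed from age 40
(biennial exams for 30 y, administrative censoring at 100): a = −0.3/y
(relaxation time ~3 y), f1 = 80 + 0.3t vs norm f0 = 80 + 0.2t (widening
allostatic load), b = 3 (stationary spread ≈ 3.9), Gompertz baseline with
level 1e-3/y at 40 and doubling time ≈ 8 y, curvature Q = 2e-5·(1+0.01t).
These magnitudes mimic a blood-pressure-like variable with realistic adult
mortality. Problem sizes: parameter recovery n = 2000 with quarterly
exams; LRT calibration 200 replicates of n = 300; latent-class recovery
n = 1000 with class f1 intercepts 4 stationary SDs apart; genetic power
20 replicates of n = 2000 at 30% genotyped, with 6-replicate means for the
genotyped-fraction sweep.

The hypothesis-testing experiments (LRT calibration; genetic power) use a
variant with Q0 = 2e-4: at the population-average curvature the quadratic
term is ~1% of total hazard, so the age-slope q1 and genotype curvature
ratio are essentially unidentified at these sample sizes and a calibration
or power experiment would be vacuous — the experiments are designed around
a marker with a substantive effect on stress resistance, as power analyses
of this model family do.

## What the generator does and does not emulate

Synthetic cohorts exercise sparse intermittent examination, left entry,
right censoring, competing information between trajectory and survival,
partial genotyping and hidden heterogeneity. They do **not** contain:
informative (outcome-dependent) visit schedules, measurement error unless
asked for, model misspecification (the fitted forms are the generating
forms), competing risks, or secular/cohort trends. Passing tests therefore
demonstrate internal correctness and calibration of the machinery, not
robustness of the model on real data, where the parametric forms are
always approximations and sensitivity analyses across forms and K are
essential practice.

## Known limitations

* The conditional-Gaussian closure is exact only for Q = 0; for Q > 0 it
  is an approximation (checked against simulation at the parameter
  magnitudes above, where it is accurate to within Monte-Carlo error).
* Exact-observation mode assumes no assay noise; the filter mode exists
  but is slower and not vectorised.
* Time-varying covariates, competing risks, informative visiting and
  nonparametric component estimation are out of scope.
* Euler event placement biases event ages by O(dt); dt = 0.05 y keeps this
  below Monte-Carlo resolution at the scales used.
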