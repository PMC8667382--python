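# Methods

## Model

A zero-inflated Bernoulli (ZIB) observation is the product of two
latent Bernoulli layers: exposure X ~ Bernoulli(ω) and, given X = 1,
occurrence Bernoulli(p); only Y = X·(occurrence) is observed. The
marginal distribution is Bernoulli(ω·p), so structural zeros
(probability 1 − ω) and sample zeros (probability ω·(1 − p)) are
indistinguishable from the likelihood alone: any factorization of the
product t = ω·p gives the same likelihood `t^m (1 − t)^(n−m)`. The
package therefore treats identification as a prior-information problem.

**Assumptions.** Observations are independent; exposure and occurrence
layers are conditionally independent given their covariates; with no
covariates, the prior supports of ω and p do not overlap (defaults
U[0, 0.5] and U[0.5, 1]), which is what separates the two zero
sources. If a user supplies overlapping supports for an intercept-only
model, the fit proceeds but attaches an explicit warning that the two
sources are only separated to the extent the priors disagree.

## Exact no-covariate posterior

With aggregate counts (m, n) and uniform priors, the joint posterior is
the likelihood truncated to the prior box. Substituting t = ω·p reduces
each one-dimensional marginal to an increment of the beta distribution
function F(·; m+1, n−m+1):

    f(ω) ∝ [F(b_p·ω) − F(a_p·ω)] / ω   on [a_ω, b_ω]
    f(p) ∝ [F(b_ω·p) − F(a_ω·p)] / p   on [a_p, b_p]

which at the default supports reduce to [F(ω) − F(ω/2)]/ω and
F(p/2)/p. Numerical choices:

- normalizing constants by adaptive quadrature (absolute and relative
  tolerance 1e−10, bounded smooth integrands);
- quantiles by Brent root finding on the quadrature CDF, xtol 1e−8 in
  parameter space;
- the singularity at 0 is removable (the CDF increment vanishes like
  x^(m+1)); the limit branch returns 0 for m ≥ 1 and the exact limit
  (b − a)(n + 1) of the unnormalized density for m = 0, instead of
  relying on floating-point cancellation;
- reports round to 2 decimals, the presentation convention used
  throughout.

The general-support form reduces exactly to the default-support form,
which is asserted in tests; the summary of the product ω·p (whose
marginal has no one-dimensional closed form) uses a 400×400 midpoint
grid over the prior box.

## MCMC for the regression model

Both parameters take logit links, `logit(ω_i) = θᵀ[1, x_i]`,
`logit(p_i) = βᵀ[1, z_i]`; an intercept column is always prepended
internally, so user matrices hold covariates only. Coefficients get
independent normal(0, σ²) priors. The prior scale is fixed at σ = 10 by
default; an optional hyperprior mode places half-normal(5) priors on
σ_θ and σ_β and samples them on the log scale. Both modes exist because
the scale hyperparameters are a genuinely open design choice; σ = 10 is
weakly informative on the logit scale for effect sizes up to the
simulation design's ±4.

A model part *without* covariates is parameterized directly by its
probability on its truncated-uniform support (a logit rescaling to the
real line with the corresponding Jacobian) rather than as an intercept
with a normal prior. This makes the intercept-only sampler target
exactly the same posterior as the quadrature module, so the two routes
can be cross-validated — they agree within Monte-Carlo error in tests.

**Sampler.** The default engine is an in-package No-U-Turn sampler:
recursive trajectory doubling with a slice variable, a divergence
threshold of 1000 on the energy error, dual-averaging step-size
adaptation toward a target acceptance statistic, and windowed diagonal
mass-matrix re-estimation during warmup. Gradients of the log
posterior are analytic (the likelihood and all priors are smooth
elementary functions) and are verified against central finite
differences at 1e−8 in tests. An adaptive random-walk Metropolis
sampler with the same draw contract serves as a gradient-free fallback.
Default configuration: 5 chains × 5000 iterations, half used for
warmup, target acceptance 0.999, maximum tree depth 25 — deliberately
conservative settings suited to the stiff geometry near the prior
boundaries. Desk-scale tests and the acceptance script use reduced
settings (2–4 chains, 600–1500 iterations, target 0.8–0.9, depth 8–10),
which the cross-validation against the exact posterior shows are
sufficient for median and interval summaries at these data sizes.

Log-likelihood evaluation stays in the log domain: log ω·p is a sum of
two log-sigmoids (via softplus) and log(1 − ω·p) goes through a stable
log1mexp branch; logits are never exponentiated first. Boundary-
incompatible parameter values yield −inf rather than exceptions so
samplers and optimizers can reject them.

**Diagnostics.** Summaries are pooled empirical medians and 2.5/97.5
percentiles per parameter. Split-R̂ (rank-normalized) and bulk
effective sample size come from arviz. Fits attach warnings (never
raise) when R̂ > 1.01 or ESS < 100; `check_convergence` exposes
configurable thresholds (defaults 1.01 / 400) and degrades to an
ESS-only report for single chains.

## Synthetic data

The regression generator draws four i.i.d. standard-normal covariates
per unit: x1, x2 drive exposure through θ = (θ0, θ1, θ2) and x3, x4
drive occurrence through β = (β0, β1, β2); the observed outcome is the
product of the two Bernoulli draws and the latent exposure labels are
returned alongside for test oracles. An option to share covariates
between parts exists for stress testing and is off by default. Each
dataset owns one seeded generator split into fixed-order sub-streams
(covariates, exposure, occurrence), so extending the design never
reshuffles earlier draws; replicate r of a scenario uses seed
`base + r`.

What the generator does *not* emulate: categorical survey covariates
(self-perceived health, replaceability), survey weighting, missingness,
or dependence between units. Passing recovery tests therefore show
correctness of the inference machinery under the generating model, not
robustness to real survey artifacts.

## Simulation harness

For each scenario the harness runs simulate → fit → summarize over
replicates and reports, per parameter, the arithmetic mean of the
posterior medians and of the 2.5% and 97.5% bounds (a literal average
of per-replicate interval endpoints, not an interval of averages).
Replicates failing a lenient convergence screen (R̂ > 1.05 or
ESS < 50) are excluded with a logged count; a row is flagged when more
than 20% drop out. The full design grid has 81 cells (β0 ∈ {0.5, 1,
2}, β1 ∈ {2, 3, 4}, β2 = 3, θ0 ∈ {−0.5, −1, −2}, θ1 ∈ {−2, −3, −4},
θ2 = −3) at the reference sample sizes 500 and 1500 with 100
replicates; tests and the acceptance script run single cells at 2–5
replicates with the reduced sampler settings, which keeps Monte-Carlo
spread of the averaged medians within about ±0.1 at n = 1500.

## Baselines

The pooled logistic comparator ignores the at-risk distinction; its
intercept-only fitted probability is exactly the sample proportion
m/n, and the package reports the Wald interval on the probability
scale, m/n ± 1.96·√(m/n·(1−m/n)/n) — the probability-scale interval is
what the proportion convention reports; coefficient-scale Wald
intervals are used whenever covariates are present. The exposed-only
comparator conditions on latent exposure labels and is available for
simulated data (or any dataset carrying such labels). Separation is
detected heuristically (non-convergence or coefficients beyond ±20
after capped IRLS iterations) and flagged as a warning rather than an
error.

## Known limitations

- Count-data zero inflation (ZIP/ZINB) and frequentist EM fitting of
  Bernoulli mixtures are out of scope.
- The no-covariate exact module supports only uniform priors; other
  priors go through the MCMC module.
- The NUTS implementation adapts a diagonal metric only; strongly
  correlated posteriors (e.g. the ω–p ridge) mix more slowly than they
  would under a dense metric, which the conservative default iteration
  counts compensate for.
- The identifiability warning is a heuristic on prior supports; it does
  not quantify partial identification.
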