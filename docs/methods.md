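# Methods

## Model

`kinbayes` models replicated isotopomer abundance time courses from stable
isotope tracer experiments (SIRM) in which neither metabolite pools nor
isotope enrichments are at steady state. For observed concentrations
`y[t,j,i]` (time point t = 1..T, replicate j = 1..m, isotopomer i = 1..n):

    log y[t,j,i] = log mu[t,i] + delta[t,j,i],   delta[t,j,i] ~ N(0, sigma_i^2)
    d mu / dt    = f(mu; exp(beta), t),          mu(0) = mu0,

where `f` is a user-specified ODE network (typically mass action over
labeled/unlabeled species), `beta` is the vector of log rate constants, and
each isotopomer has its own log-scale error variance `sigma_i^2`.
Multiplicative log-normal noise is the standard error model for abundance
data spanning orders of magnitude; working with `beta = log k` removes the
positivity constraint on rate constants.

Assumptions worth stating plainly: errors are independent across times,
replicates and isotopomers (no replicate random effect, no autocorrelation);
the mean trajectory is strictly positive wherever observed; the network
structure `f` is known and only its rate constants are inferred.

## Priors

* `beta ~ TruncNormal(xi, Lambda, [zeta_l, zeta_u])`. Mean, covariance and
  box bounds encode kinetic knowledge (literature ranges, BRENDA-type enzyme
  data). The helper `BetaPrior.from_ranges` builds a diagonal `Lambda` from
  per-parameter ranges using sd = range/4 when no sd is given.
* `sigma_i^2 ~ InvGamma(alpha*, kappa*)`, one common prior shared by all
  isotopomers (variance shrinkage across the metabolite ensemble). The
  hyperparameters are empirical-Bayes estimates, moment-matched to the grid
  of per-cell sample variances `s_it^2` of the log data:

      alpha* = sbar2^2 / [ sum (s_it^2 - sbar2)^2 / (nT - 1) ] + 2
      kappa* = sbar2 (alpha* - 1),      sbar2 = mean of the s_it^2,

  so the prior mean equals `sbar2` and `alpha* > 2` always. They are
  computed once and held fixed during sampling. With m = 3 replicates the
  raw per-cell variances are extremely noisy; the conjugate update pulls
  each posterior variance between its raw residual estimate and the
  ensemble mean (a convex combination — tested as an invariant).

The inverse gamma is parameterized shape/scale with density proportional to
`x^(-a-1) exp(-k/x)`. The likelihood and both prior kernels omit their
additive normalizing constants; every Metropolis ratio, HDI and credible
value is invariant to this convention.

## Posterior sampling

A Gibbs scheme alternates:

1. **beta sweep** — each component in fixed cyclic order 1..d gets a
   Gaussian random-walk Metropolis update against the conditional log
   posterior. The proposal variance for component i is the conditional
   variance under the chain's running covariance `C`:
   `D_i = C_ii - C_{i,-i} C_{-i,-i}^{-1} C_{-i,i}` (computed for all i at
   once as `1/diag(C^{-1})`, which is the same Schur complement). `C` is
   frozen at `C0` for the first `l0` iterations and afterwards follows the
   adaptive-Metropolis rule `C = s_d cov(history) + s_d eps I`, with the
   history covariance maintained by a Welford recursion (mathematically
   identical to recomputing `cov` over the stored history). The covariance
   used within a sweep is frozen at sweep start.
2. **delayed rejection** — from iteration `dr_onset` on, a rejected
   first-stage proposal triggers a second proposal with variance
   `gamma * D_i` accepted with the two-stage probability

       min{1, [pi(y2) q1(y1|y2) (1 - a1(y2,y1))] / [pi(x) q1(y1|x) (1 - a1(x,y1))]},

   where `a1` is the stage-1 acceptance probability. The symmetric
   stage-2 densities cancel; the stage-1 density ratio does not and is
   included — dropping it breaks reversibility, which the 5-D Gaussian
   moment test catches immediately.
3. **variance updates** — each `sigma_i^2` is conjugate:
   `InvGamma(alpha* + mT/2, kappa* + SS_i/2)` with `SS_i` the residual sum
   of squares of isotopomer i at the current `beta`.

Defaults (all config-overridable): `s_d = 2.4^2/d`, `eps = 1e-6`,
`C0 = 0.1 diag(Lambda)`, `gamma = 0.25` (smaller second-stage steps),
initial `beta = xi`, initial `sigma_i^2` = pooled per-isotopomer sample
variance of the log data. Out-of-box proposals are rejected through the
truncated prior (no reflection), which keeps the kernel valid without
Jacobian bookkeeping and costs one cheap bound check before any ODE solve.
Production-scale default iteration structure is 15,000 iterations with
adaptation from 3,000 and delayed rejection from 4,000.

ODE integration uses LSODA (stiff-capable, adaptive) with rtol 1e-6, atol
1e-9, through the low-overhead `scipy.integrate.odeint` interface; the
declarative mass-action networks evaluate their rate law allocation-free.
States negative by less than 1e-7 (solver-tolerance undershoot on decaying
pools) are clipped to zero; anything more negative raises a
model-misspecification error. Observed cells with mean below 1e-300 are
domain errors rather than floored — silent flooring would bias exactly the
low-abundance isotopologues that already fit worst. An ODE failure at a
proposed `beta` is treated as a rejection of that proposal, not as a fatal
error; failures are counted on the chain object.

## Inference summaries

* **HDI** — shortest contiguous window containing `ceil(level*L)` sorted
  draws (unimodal convention; the density-ordering definition is the
  theoretical object, but a window scan is deterministic given the sample
  and needs no density estimate). Exactness is tested against a brute-force
  scan of every window.
* **Credible value** — `p = 1 - max{alpha : 0 not in HDI_alpha}`, found by
  bisection over the level (tolerance 1e-4). Two-sided by construction;
  `p < 0.05` is called significant. For Gaussian posteriors
  `p = 2 Phi(-|mean|/sd)`, the analytic anchor used in the tests.
* **Geweke diagnostic** — z-score comparing the first 10% against the last
  50% of the retained chain, with Bartlett-tapered spectral-density-at-zero
  variance estimates (lag window `sqrt(n)`). `|z| < 1.96` is flagged as
  consistent with convergence.
* **Flux bands** — a named flux (e.g. a mass-action reaction rate) is
  evaluated along the ODE solution at every retained posterior draw; the
  band is the pointwise central 95% interval around the pointwise mean.

## Two-group comparison

To test whether one rate constant differs between groups (H0:
`beta_k^(1) = beta_k^(2)`), both groups are fitted jointly under the
reparameterization `eta_k = beta_k^(1) - beta_k^(2)`; group 2's k-th
parameter is never sampled directly but reconstructed as
`beta_k^(1) - eta_k`. The joint vector `(beta^(1), beta^(2)_{-k}, eta_k)`
runs through the same AM+DR sweep engine; each group keeps its own error
variances and its own empirical-Bayes hyperparameters (the groups are
modeled with separate variances, so pooling their variance priors would
leak information across arms). `eta_k` gets a `Normal(0, Lambda_kk)` prior:
"the variance of `beta_k^(1)`" is read as the *prior* variance, since no
posterior variance exists before fitting; the choice is switchable via
`eta_prior_var`. The decision rule is `credible value < 0.05`, equivalent
(within bisection tolerance) to the 95% HDI of `eta_k` excluding zero.
Positive `eta_k` means a larger rate constant in group 1, and reports state
the direction explicitly. Testing several parameters means independent
one-at-a-time fits; no multiplicity correction is applied, and reports
should say so.

## Synthetic data and the shipped studies

`simulate_dataset` draws data exactly from the observation model: ODE means
at the true `beta`, then `y = exp(log mu + N(0, sigma_i^2))` on a complete
T x m x n grid. Per-isotopomer variances are either fixed or drawn once per
dataset from `InvGamma(shape, scale)`; the default (shape 5, scale 0.2,
mean 0.05, i.e. about 22% CV) is a realistic bench value for isotopologue
quantification. The default design is m = 3 replicates at times
0.5, 1, 2, 4, 6, 8 hours.

What the generator does **not** emulate: replicate-level random effects,
time-correlated drift, missing cells, natural-abundance contamination, or
model misspecification (data are generated from the same network that is
fitted). Passing recovery tests therefore demonstrates correctness of the
inference machinery under the stated model, not robustness to real-data
violations of it.

Two exemplar networks ship with documented truths:

* `decay2` — A -> B -> sink, k = (0.5, 0.3)/h, A0 = 10. Closed forms make
  it the unit-test workhorse and the two-group study substrate.
* `pool3_mini` — a closed 8-state, 5-parameter labeled/unlabeled
  tracer-dilution network (medium glucose uptake, reversible
  glucose/serine exchange in both label states, an unlabeled exogenous
  serine source, terminal purine pools), k = (0.4, 0.6, 0.15, 0.5, 0.7)/h.
  Total mass is conserved (closed mass action), which the tests exploit.

The shipped simulation studies use a scaled-down sampler configuration
(2,500 iterations, adaptation from 500, delayed rejection from 800, 1,000
discarded) that mirrors the production structure at a size these small
networks resolve well; posterior summaries are stable against doubling the
chain length. The recovery study (30 simulate-and-fit runs, m = 3) reports
the per-parameter averaged error, its standard error across runs, and
whether zero lies within +/-2 se; it is run on `pool3_mini`, the exemplar
that matches the three-pool structure such studies are meant to emulate.
The two-group study (20 runs per scenario on `decay2`, true differences 0
and 0.35) reports HDI coverage of zero under the null and rejection rate
under the alternative.

## Known limitations

* For very sharply identified parameters the posterior mean carries a small
  inherent finite-sample bias (about 1% of the rate constant for `decay2`'s
  first parameter at the default design — present identically in a
  frequentist least-squares fit, so a property of the design's information
  content, not of the sampler). With 30 runs the +/-2 se recovery box is
  then narrow enough to resolve this bias, so such a parameter can fail
  the coverage check even though the estimator is excellent in absolute
  terms. The same phenomenon motivates reading recovery tables alongside
  the absolute error columns.
* At m = 3 the two-group test is mildly anticonservative at desk scale
  (null rejection somewhat above nominal 5% in the shipped study); the
  credible value is a posterior-belief summary, not an exact frequentist
  p-value.
* The HDI convention assumes unimodal posteriors; multimodal posteriors
  would need the density-ordering definition and are out of scope, as are
  vector-valued `eta` tests (multi-dimensional credible regions).
* Geweke windows (10%/50%) and the Bartlett lag truncation are the
  package's defaults; the diagnostic cites convergence consistency, never
  proof.
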