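# kinbayes

Bayesian non-steady-state kinetic modeling of stable-isotope-resolved
metabolomics (SIRM) time courses.

SIRM experiments follow labeled substrates (e.g. ¹³C₆-glucose) through a
metabolic network by measuring isotopomer abundances over time in a few
replicates. Fitting the rate constants of the underlying ODE network is
hard: many parameter sets fit equally well, replicate counts are tiny, and
weighted-least-squares fits give no usable uncertainty, so groups (cancer
vs. normal, treated vs. control) cannot be compared rigorously. `kinbayes`
addresses this for experimentalists and biostatisticians with a fully
Bayesian treatment of the model

```
log y_tji = log μ_ti + δ_tji,   δ_tji ~ N(0, σ_i²)
dμ/dt     = f(μ; e^β, t)
```

with

* a **truncated multivariate normal prior** on the log rate constants β
  (expert knowledge as mean/covariance/bounds),
* an **empirical-Bayes inverse-gamma shrinkage prior** shared by all
  per-isotopomer variances σ_i² — `α* = s̄⁴/disp + 2`, `κ* = s̄²(α*−1)`
  from the grid of per-cell sample variances — which stabilizes variance
  estimation at m ≈ 3 replicates,
* a **Gibbs sampler** alternating conjugate InvGamma(α* + mT/2,
  κ* + SS_i/2) variance draws with **component-wise adaptive Metropolis**
  updates of β (proposal variance = Schur complement
  `D_i = C_ii − C_{i,−i}C_{−i,−i}⁻¹C_{−i,i}` of the adapted covariance
  `C = s_d·cov(history) + s_d·ε·I`) plus **delayed rejection** (a second,
  γ-scaled proposal with the reversibility-preserving two-stage acceptance),
* a **two-group hypothesis test** via the reparameterization
  `η_k = β_k⁽¹⁾ − β_k⁽²⁾`, summarized by the 95% highest-density interval
  and a **credible value** `p = 1 − max{α : 0 ∉ HDI_α}` (two-sided;
  `p < 0.05` significant),
* highest-density intervals, Geweke convergence diagnostics, and posterior
  credible bands for metabolic fluxes over time.

See `docs/methods.md` for the full model, the numerical choices, and known
limitations.

## Worked example

Simulate a two-state tracer network (A → B → sink, true log rate constants
β = (log 0.5, log 0.3) ≈ (−0.693, −1.204)), fit it, and compare two groups
differing in `k_ab` by 0.35 on the log scale:

```bash
kinbayes simulate --model decay2 --seed 11 --out demo.csv --truth-out truth.json
printf 'n_iter: 2500\nburn_in: 1000\nl0: 500\ndr_onset: 800\n' > cfg.yaml
kinbayes fit --data demo.csv --model decay2 --config cfg.yaml --seed 12 --out fit
```

```
parameter      mean       sd  hdi_0.95_lower  hdi_0.95_upper  geweke_z
     k_ab -0.696835 0.017383       -0.732594       -0.665361  0.102028
  k_b_out -1.176360 0.039604       -1.255863       -1.100489 -0.306175
```

Both posterior means sit within one posterior sd of the truth, the 95%
HDIs cover it, and |Geweke z| < 1.96 is consistent with convergence.

```bash
kinbayes simulate --model decay2 --beta "[-1.0431, -1.204]" --seed 13 --out demo2.csv
kinbayes compare --data1 demo.csv --data2 demo2.csv --model decay2 \
    --param k_ab --config cfg.yaml --seed 14 --out cmp
```

```
parameter  credible_value  hdi95_lower  hdi95_upper  significant       direction
     k_ab             0.0     0.297224     0.397198         True group1 - group2
```

The 95% HDI of the group difference η = β_k⁽¹⁾ − β_k⁽²⁾, (0.30, 0.40),
covers the true difference 0.35 and excludes 0; the credible value below
the 1e-4 bisection resolution calls the difference significant. Every run
also writes a JSON manifest (seed, config echo, input digests) and the full
chain as CSV.

The same functionality is available as a library (`simulate_dataset`,
`run_gibbs_sampler`, `fit_two_group`, `hdi`, `credible_value`,
`compute_flux_trajectory`, ...) for scripted analyses.

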