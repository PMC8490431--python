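# odah — one-shot distributed hurdle regression for multi-site count data

Clinical research networks hold patient-level data in many health systems
that cannot pool rows across sites. For zero-inflated count outcomes (number
of avoidable hospitalizations, adverse-event counts, visit counts — mostly
zeros, occasionally several), the standard privacy-preserving analysis is a
fixed-effects meta-analysis of per-site fits, which becomes badly biased
exactly where multi-site data matter most: rare outcomes and low event
rates, where individual sites barely see enough events to fit a model.

This package implements **ODAH** (one-shot distributed algorithm for hurdle
regression): a surrogate-likelihood estimator that fits a Poisson–Logit
hurdle model across sites in at most two rounds of aggregate-only
communication and tracks the pooled (all-rows) estimate to within ~0.1%
even in regimes where meta-analysis is off by ~10%.

## Model and estimator

The hurdle model splits the outcome in two independent parts:

    logit P(y_i > 0) = X_i'β            (which patients have any event)
    y_i | y_i>0 ~ ZTP(λ_i),  log λ_i = Z_i'γ    (how many, given any)

with ZTP the zero-truncated Poisson. The log-likelihood separates as
L(β, γ) = L₁(β) + L₂(γ) with a block-diagonal Hessian, so the two
coefficient vectors are estimated independently (Newton–Raphson on analytic
scores and Hessians).

Across K sites with lead site 1, the surrogate log-likelihood per component
is

    L̃(θ) = L_lead(θ) + ⟨∇L_N(θ̄) − ∇L_lead(θ̄), θ⟩
            + ½ (θ − θ̄)' [∇²L_N(θ̄) − ∇²L_lead(θ̄)] (θ − θ̄)

where θ̄ is an inverse-variance meta-analysis of per-site estimates
(round 1) and ∇L_N, ∇²L_N are sample-size-weighted averages of per-site
scores and Hessians evaluated at θ̄ (round 2). The ODAH estimates maximize
L̃; variances come from the inverse surrogate information. Only
fixed-dimension aggregates ever leave a site.

See `docs/methods.md` for derivatives, numerical guards, the degenerate
rare-event cases, and the synthetic cohort design.

## Worked example

Five simulated sites (N = 50,000, 2.4% prevalence, event rate 0.03, true
slopes (−1, 1) in both components), distributed fit vs. the pooled gold
standard:

```python
import numpy as np
from odah import (SimulationSetting, make_site_datasets, fit_hurdle,
                  summarize_fit, meta_initialize, compute_gradients,
                  aggregate_gradients, odah_solve, pooled_fit)

s = SimulationSetting(name="demo", K=5, N=50_000, n_lead=10_000,
                      beta0=-3.7, gamma0=-3.6, seed=42)
sites = make_site_datasets(s, 0)

# round 1: local fits -> meta-analytic initial estimates
fits = [fit_hurdle(d) for d in sites]
init = meta_initialize([summarize_fit(f, d) for f, d in zip(fits, sites)])
# round 2: gradients at the initial estimates -> surrogate maximization
agg = aggregate_gradients([compute_gradients(d, init) for d in sites])
res = odah_solve(sites[0], agg, init)

pooled = pooled_fit(sites)
print(res.params.gamma)     # [-0.5564 -0.883   0.8262]
print(pooled.params.gamma)  # [-0.5563 -0.8831  0.8262]
```

The distributed γ estimate agrees with the pooled one to the fourth decimal
(relative deviation of the slope γ₂: 0.007%), while only site 1's rows and
3-vectors/3×3 matrices from the other sites were used. The fitted slopes
(−0.88, 0.83) sit within two standard errors (≈0.09, 0.14) of the true
(−1, 1) at this sample size.

There is also a scikit-learn-style estimator for single-dataset fits
(`HurdleRegressor().fit(X, y)` with `beta_`, `gamma_`, `predict`) and a CLI
mirroring the file exchanges of the protocol
(`odah simulate / fit-local / init / gradients / solve / study` — one JSON
file per site per round; run `odah --help`).

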