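# dieltrsf

Temporal resource-selection analysis of camera-trap data: do mammals shift
their activity along the 24-hour light–dark cycle as their local
environment urbanizes?

`dieltrsf` treats diel time as a selectable resource. Each detection event
from a camera-trap network falls into one of five sun-defined categories —
day, dawn, dusk, night, and deep night (solar nadir ± 1 h) — whose
availability in hours varies with date and latitude. A hierarchical
Bayesian multinomial (softmax) regression with availability offsets then
measures *selection* for each category relative to daytime, as a function
of urban covariates: available greenspace, impervious cover, vegetation
cover, human population density, and daily mean temperature.

The package is aimed at urban-wildlife ecologists running multi-city
camera networks, and at methodologists who want a tested reference
implementation of a diel selection model with a synthetic-data generator
for calibration experiments.

## The model

For detection event *i* with diel category *y_i* ∈ {1..K}, K = 5 and
k = 1 ≡ day as the reference:

    y_i ~ Categorical(φ_i)
    φ_ik = exp(λ_ik) / Σ_k exp(λ_ik)
    λ_i1 = log(α_i1)
    λ_ik = x_iᵀ β_k + b_{c[i],k} + log(α_ik),   k > 1

where α_ik is the hours category k offers in event *i*'s solar cycle (an
offset), x_i are city-mean-centered covariates scaled by their global
standard deviation, and b_{c,k} is a random intercept for the event's
city. With all effects zero, φ_k = α_k / Σα — use proportional to
availability — so exp(β_jk) > 1 means selection for category k (and < 1
avoidance) per one-SD covariate increase, relative to day.

Priors: β_jk ~ Laplace(0, rate π) (a Bayesian LASSO), π ~ U(0.001, 10),
b_{c,k} ~ Normal(μ_k, precision τ_k), μ_k ~ N(0, 10), τ_k ~ Gamma(1, 1).
Fitting is by adaptive Metropolis-within-Gibbs MCMC (numba-compiled), with
the classic Gelman–Rubin R̂ < 1.1 convergence criterion. The default
protocol is 14 chains, 20,000 burn-in, thinning by 7, 75,000 retained
draws; pass smaller settings for interactive work.

## Worked example

```python
import numpy as np
from datetime import date
from dieltrsf import (GeoPoint, compute_schedule, SimulationTruth, simulate,
                      build_model_data, SamplerConfig, sample_posterior,
                      odds_ratio_table)

# 1. Diel availability in Chicago on 1 May 2017
s = compute_schedule(date(2017, 5, 1), GeoPoint(41.8, -87.6, "America/Chicago"))
print({k: round(v, 2) for k, v in s.alpha.items()})
# {'day': 13.96, 'dawn': 1.86, 'dusk': 1.86, 'night': 4.32, 'deep_night': 2.0}

# 2. Simulate a 5-city network where impervious cover drives night selection
beta = np.zeros((2, 4)); beta[1, 2] = 0.6      # impervious -> night
truth = SimulationTruth(
    n_cities=5, sites_per_city=(24,)*5,
    start=date(2017, 4, 1), end=date(2017, 6, 29),
    site_covariates=("greenspace", "impervious"), use_temperature=False,
    beta=beta, events_per_site_day=0.185, seed=11)
ds = simulate(truth)                            # 1,950 events

# 3. Fit and summarize
data = build_model_data(ds.ledger, truth.covariate_names)
samples = sample_posterior(
    data, SamplerConfig(n_chains=4, burn_in=2000, thin=1, kept_total=5000, seed=1))
print(samples.max_rhat())                       # 1.006  (converged)
print(np.median(samples.flat("beta"), axis=0).round(2)[1])
# [ 0.05 -0.05  0.52  0.05]   <- night coefficient ~0.52 vs truth 0.6

alpha_bar = ds.ledger[[f"alpha_{c}" for c in
    ("day", "dawn", "dusk", "night", "deep_night")]].mean().to_numpy()
print(odds_ratio_table(samples, alpha_bar,
                       covariate_names=["greenspace", "impervious"]))
```

The odds-ratio table (nocturnal use, i.e. night + deep night combined):

```
 covariate  shift_sd  or_median  or_lower  or_upper  excludes_one
greenspace       1.0      0.968     0.881     1.066         False
greenspace       2.0      0.938     0.778     1.136         False
impervious       1.0      1.502     1.318     1.710          True
impervious       2.0      2.332     1.813     3.015          True
```

Animals at sites one global SD higher in impervious cover are ~50% more
likely to be active at night (95% CrI 1.32–1.71, excluding 1), exactly the
effect the generator planted; greenspace, simulated with no effect, shows
odds ratios straddling 1.

A `dieltrsf` command-line tool mirrors this flow for CSV inputs:
`dieltrsf simulate | categorize | fit | odds-ratios | predict`.

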