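# Methods

## Diel categories and availability

A diel cycle runs solar noon to solar noon, so the deep-night window
(solar nadir ± 1 h) is never split across cycles. Boundaries are
sun-altitude events computed with an apparent-solar-longitude algorithm of
the NOAA/Meeus class (declination and equation of time from truncated
series; event times solved iteratively from the hour angle). Series
accuracy is well under a minute over 1900–2100; agreement with other
common implementations (e.g. the suncalc event set) is expected within
about 2 minutes, dominated by refraction conventions.

Category definitions:

* **dawn** — morning astronomical-twilight start (sun center −18°) to the
  moment the sun's bottom edge touches the horizon. "Bottom edge touches
  the horizon" is mapped to a center altitude of −0.3° (refraction plus
  semidiameter), the convention of the suncalc `sunriseEnd`/`sunsetStart`
  events.
* **day** — end of dawn to the evening −0.3° crossing.
* **dusk** — evening −0.3° crossing to the end of evening astronomical
  twilight (−18°), i.e. when it is dark enough for astronomical
  observations. The evening threshold mirrors the morning one; no other
  threshold is defensible for "astronomical darkness".
* **deep night** — nadir ± 1 h exactly (availability 2.0 h by
  construction).
* **night** — the remaining dark intervals on both sides of deep night.

Intervals are half-open [start, end): a timestamp exactly on a boundary
belongs to the later category. All arithmetic is on the UTC timeline;
local civil timestamps are converted through the IANA tz database, so
daylight-saving transitions cannot distort availabilities.

Degenerate geometries are handled in two ways. Where the sun never
reaches −18° (or never rises), a `TwilightUndefinedError` names the
missing event — there is no silent fallback to another twilight scheme.
In the narrow marginal band (|lat| ≈ 47–50° near the June solstice) where
twilight exists but the −18° crossing falls inside the deep-night window,
the twilight boundary is clipped to the window so the five categories
still partition the cycle; night availability is then zero there. Sites
of the emulated study design stay below 44° latitude, where night
availability is always positive (the model requires log α finite).

Availability α is computed from the solar cycle containing the event, not
the civil day; the cycle frame is what keeps the nadir window contiguous.

## Event processing

A detection event is all photos of one species at one station grouped by
the chain rule: a photo opens a new event iff its gap to the *previous
photo* exceeds the 15-minute window. The prevailing alternative —
measuring gaps from the event's first photo — is available as
`rule="anchor"` for sensitivity analyses. The event timestamp is its
first photo. Trap nights are floor(interval length in nights) summed over
deployment intervals; overlapping intervals at one station are an error.
An event's daily mean temperature is that of its local civil date (the
date of the timestamp in the site's timezone, also for after-midnight
events) and city; missing temperatures are flagged with NaN rather than
dropped unless requested.

## Covariates

Rasters are plain numeric grids in a user-supplied metric projection; the
package computes NDVI ((NIR−Red)/(NIR+Red), no-data propagated), buffer
proportions (cell-center-in-circle membership, configurable predicate,
NDVI > 0.2 as the vegetation default), and the model's scaling:
city-mean centering followed by division by the covariate's global
standard deviation (`GroupMeanScaler`, with inverse transform). The
global SD for temperature is taken over all detection events of the
species. Acquisition of land-cover, imagery, or census products is out of
scope; users supply grids or a prepared covariate table.

## Model and sampler

See the README for the likelihood and priors. Parameter conventions
follow JAGS, which the phrasing of the priors presumes but does not
state: Laplace(0, π) is a *rate* (density (π/2)e^{−π|x|}), Normal(μ, τ)
uses a *precision* τ, and Normal(0, 10) for μ_k is variance 10. The
reference category's coefficients are pinned to zero (β_{j,1} =
b_{c,1} = 0), which is what identifies the softmax.

The sampler is adaptive Metropolis-within-Gibbs, compiled with numba:

* β coefficients of each non-reference category are one random-walk block
  per sweep; step sizes adapt toward ~0.28 acceptance during burn-in only
  (so the kept chain is Markov);
* city intercepts are scalar random-walk updates (target 0.44);
* μ_k and τ_k have conjugate Normal and Gamma full conditionals and are
  drawn exactly by Gibbs — exact updates are preferable to slice steps
  where conjugacy holds;
* π has a bounded-domain slice update (its full conditional is a
  truncated Gamma).

The categorical likelihood is maintained incrementally: per-row exp(λ)
and row sums are cached, so a proposal costs one exp and one log per
affected row; caches are refreshed every 200 iterations against
floating-point drift. λ is bounded in this model (log availability plus a
few units of effect), so linear-space sums cannot overflow; proposals
pushing |λ| past 60 are rejected. Chains get deterministic seeds derived
from one master seed, making every fit exactly reproducible.

Convergence is the classic Gelman–Rubin potential scale reduction factor
(R̂ = sqrt(V̂/W) with V̂ = (n−1)/n·W + B/n), threshold 1.1, computed per
parameter; rank-normalized split-R̂ is additionally available via ArviZ
(`PosteriorSamples.split_rhat`). Non-convergence warns and flags the
result; it never silently discards draws. If a species has no events in
some category the fit proceeds prior-dominated with a warning naming the
empty categories.

Posterior draws are stored as an `.npz` container with named arrays,
chain/draw dimensions, the sampler configuration, and the seed.

## Inference

All summaries are computed per posterior draw through the same softmax
code path and summarized by the median and central (equal-tailed) 95%
interval. Nocturnality is φ_night + φ_deep_night. Odds ratios for a
+1 or +2 SD covariate shift hold the other covariates at 0 (the
city-centered scale), fix availability at a caller-supplied vector
(typically the species' mean availability), and use the population-level
intercept draws (μ_k) unless a city is named; each choice is an argument,
since reasonable analyses differ here. The among-city summary draws a
fresh intercept from Normal(μ_k, precision τ_k) per posterior draw, so
its interval widens as among-city precision falls. Plot helpers (stacked
bars of activity profiles) are provided but the numeric tables are the
tested surface.

## Synthetic data

The generator emulates the target study design: 10 cities, 24–113 sites
per city (mean ≈ 45), latitudes 30–44°N (the emulated cities span Austin
to Madison), a Jan 2017–Dec 2018 window, sinusoidal city temperature
seasonality with noise, and Poisson event counts per site-day (the study
carries no abundance model; the rate is plumbing). Covariates are drawn
with modest between-city mean differences and larger within-city spread,
matching designs that deliberately sample an urbanization gradient within
each city. Events draw a category from the model's softmax (true
coefficients, that site-day's availabilities), a timestamp uniform within
the category's intervals (proportional allocation across the two night
segments), and become photo bursts inside the 15-minute window; events
closer than the window to their predecessor are discarded so that
deduplication recovers the generated ledger exactly.

What the generator does *not* emulate: imperfect detection, lure effects,
camera failures, spatial autocorrelation beyond the city level, species
interactions, or real land-cover marginals. Passing calibration tests
therefore demonstrates the correctness of the estimator under the model's
own assumptions, not robustness to their violation.

Two standard conditions are exported. `recovery_truth()` — 5 cities × 24
sites, 90 spring days, 2 covariates, ~2,000 events — is sized so dozens
of refits run on one CPU while preserving the hierarchical structure.
`null_calibration_truth()` — ~10,000 events, all effects zero — checks
the availability-proportional null and that a fitted model finds no
selection. The reduced sampler protocol used with them (4 chains, 2,000
burn-in, 5,000 kept) is a scaled-down version of the default 14-chain
protocol.

## Numerical and design notes

* Softmax is computed with max-subtraction; row sums are within 1e-12.
* Log-likelihood matches a brute-force oracle to 1e-10 on small
  instances (tested).
* Boundary instants in schedules are exact partition points by
  construction; availability sums match the cycle length to well under a
  second.
* `kept_total` need not divide by `n_chains`; per-chain counts are the
  ceiling, so a few extra draws may be retained.
* The event-grouping window, NDVI threshold, buffer radii, and greenspace
  class predicate are configuration, with the study's values as defaults
  (15 min, 0.2, 500/1000/1500 m by species home range, and a
  user-supplied class set respectively).

## Known limitations

* No polar or high-latitude support: the five-category scheme is
  undefined without astronomical twilight, and the package raises rather
  than substituting civil or nautical thresholds.
* The sampler is single-machine and sequential over chains; the full
  default protocol on tens of thousands of events is an hours-scale run.
* Temperature scaling in the generator uses city-day means rather than
  event weights, a negligible difference at realistic event rates but not
  exactly the pipeline's event-level convention.
* Odds ratios depend on the availability vector at which they are
  evaluated; comparisons across studies must fix that convention.
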