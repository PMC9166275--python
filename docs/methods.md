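# Methods

`iguanapop` fits and projects a Bayesian state-space logistic model for a
harvested population monitored by annual abundance surveys. It was built
around the Grand Cayman green iguana (*Iguana iguana*) control programme —
eight August surveys 2014–2021, an islandwide cull from October 2018 — but
every component takes general survey series and harvest schedules.

## The model

**Process layer.** True abundance `N_t` (August, post-reproduction, all age
and sex classes pooled) evolves by a discrete-time logistic
surplus-production update with removals and multiplicative lognormal
process noise:

    N_{t+1} = max(0, f(N_t, h_t) * exp(eps_t)),    eps_t ~ Normal(0, sigma_proc^2)

`K` is the carrying capacity (individuals), `r_max` the maximum intrinsic
growth rate (per year), `sigma_proc` the log-scale process SD capturing
environmental stochasticity and model misspecification. Harvest enters as a
rate `h_t` (removals `H_t = h_t * N_t`) or as a total count.

**Harvest ordering.** Two discretisations of `f` are provided behind the
`timing` flag, and the choice matters more than any other numerical detail:

- `escapement` (default): removals are taken from the surveyed abundance
  first and the escapement `S_t = N_t(1 - h_t)` grows logistically,
  `f = S_t + r_max S_t (1 - S_t/K)`. A sustained rate above
  `r_max / (1 + r_max)` (~0.58 at `r_max` = 1.35) drives extinction. This
  matches the programme's operation — each August survey sets a quota that
  is hunted before the next breeding season — and is the only ordering
  consistent with the management thresholds the programme uses (rates above
  0.6–0.7 collapse the population to the 10⁴ scale within a decade).
- `simultaneous`: the classical Schaefer form
  `f = N_t + r_max N_t (1 - N_t/K) - H_t`. It carries the textbook
  sustained-yield identities (positive equilibrium `K(1 - h/r_max)` for
  every `h < r_max`), which also means no rate below 1 can ever extirpate a
  population with `r_max > 1`; use it for yield theory, not for projecting
  this cull.

Both orderings floor at zero: harvesting more animals than exist is
extinction, not an error. Under the escapement map, growth is
overcompensatory — `f` decreases in `S` beyond `K(1 + r_max)/(2 r_max)` —
so at very high density a larger cull can *raise* next year's abundance;
monotonicity of abundance in harvest holds only on the rising branch.

**Derived quantities.** The maximum sustained harvest rate is the Schaefer
identity `h_msy = r_max / 2`, summarised draw-by-draw from the posterior,
and the low-density doubling time is `ln 2 / r_max * 12` months.
`harvest_needed(N, h)` uses a ceiling so the realised rate is at least the
target.

**Observation layer.** The survey estimate `y_t` is lognormal with median
`N_t` and log-scale SD `tau_t = sqrt(ln(1 + CV_t^2))` fixed from the
survey's own `CV_t = SE_t / y_t` — the same convention as the lognormal
confidence intervals the survey tables print. Observation SDs are *not*
estimated; the surveys' bootstrapped SEs are taken at face value.

**Priors.** `K ~ Uniform(900000, 2000000)`, `r_max ~ Uniform(0.5, 2.0)`
(the published bounds for this population); `sigma_proc ~ Uniform(0.01,
1.0)` — the package's own choice where the study is silent: wide enough to
be data-dominated, bounded away from 0 to avoid a degenerate process layer;
`ln N_0 ~ Normal(ln y_0, tau_0^2)`, i.e. lognormal centred on the first
survey with its own survey spread (the prior is placed on the log state, so
no Jacobian correction applies to the sampled coordinate).

A structural consequence worth knowing: the support rule "a non-positive
deterministic prediction has no lognormal successor" truncates parameter
combinations that would let a high latent state crash below zero. When the
observations carry almost no information (a prior-predictive-style check
with CVs inflated 100-fold), the `K` marginal reverts to its prior but the
`r_max` marginal is pulled visibly below its prior mean by this truncation.
That is a property of the posterior itself — an independent ensemble
sampler reproduces it — not of the sampler.

## Sampling

Adaptive random-walk Metropolis-within-Gibbs over the scalar blocks
`(K, r_max, sigma_proc, ln N_0 … ln N_{T-1})`, all chains advanced in
lock-step as vectorised numpy operations. Proposal scales adapt toward a
44% acceptance rate in batches of 50 iterations during burn-in only
(Robbins–Monro step `min(0.05, 1/sqrt(batch))`) and are frozen afterwards,
so the retained chain is Markovian. Proposals outside prior support are
rejected outright, keeping the uniform priors exact. Starting points are
drawn from the priors (rejecting infinite-posterior states), latent paths
initialised at the observed series with jitter. Defaults: 4 chains ×
50,000 iterations, first 25,000 discarded (~25 s on one CPU for the
packaged 8-survey series). Convergence is gated on the split-chain
rank-normalised statistic (via ArviZ) below 1.05 for `K` and `r_max`; a
block that accepts nothing after adaptation raises a diagnostic error
rather than returning draws.

The sampler was validated against an independent affine-invariant ensemble
sampler (emcee) run on the identical log-posterior: posterior means of
`K`, `r_max`, `sigma_proc` agree well within Monte-Carlo error (≤ 0.05
posterior SDs on the packaged fit); the log-posterior itself is checked
against a brute-force scipy density sum to 1e-8 relative.

## Projection

Each retained draw is projected forward from **its own** latent terminal
state with its own parameters, so state and parameter uncertainty propagate
jointly. Scenario bands draw `h ~ Uniform(lower, upper)` independently for
every projected year by default; a per-trajectory mode (one rate per
future) is available — which the original analysis used is not knowable
from the published description, and per-year redraw is the default because
it matches rates being regenerated within the simulation. Process noise
stays on during projection (the published forecast spreads, with SDs
exceeding means at long horizons, are only attainable with it); it can be
disabled for skeleton plots. First-passage summaries (`time_to_threshold`)
report per-trajectory crossing years, use each draw's own `K` when the
threshold is "K", and treat never-crossing trajectories as censored.

## Synthetic studies and the recovery harness

`generate_study` simulates the full hierarchy the sampler assumes: latent
trajectory with process noise, removals proportional to abundance, then
lognormal survey estimates (median-centred on the *latent*, not the
deterministic, states) with `SE = CV * estimate`. The default CV design
copies the eight empirical CVs of the packaged series (0.19–0.42), and the
iguana-like preset uses `K = 1.3e6`, `r_max = 1.3`, `sigma_proc = 0.05`,
`N0 = 250000` with the cull pattern 0/0/0/0/0.63/0.57/0.37 — the study
conditions, not tuning knobs. `recovery_experiment` runs
simulate-then-refit replicates and reports bias, RMSE and 95%-interval
coverage per parameter, flagging (never dropping) replicates that fail the
convergence gate. At the empirical CVs, 20 replicates with 2 × 20,000
iterations give full coverage of `K` and `r_max` and ~3% relative bias on
`r_max`.

What the generator does **not** emulate: the distance-sampling /
*N*-mixture estimation that produces the survey estimates (detection
probability, bootstrap SEs), within-year harvest dynamics (monthly
reporting gaps, the 2020 lockdown), and any age/sex or spatial structure.
Passing recovery tests therefore show the estimator is consistent with its
own assumptions at realistic precision — not that those assumptions hold
for the real survey pipeline. A cautionary result from the negative
control: at survey CVs near 0.4 the observation layer can absorb even a
scrambled survey series, so misuse is only cleanly detectable (as a
process-SD blow-up) when surveys are precise.

## What the packaged-data fit does and does not reproduce

With the printed annual harvest rates (0 for 2014→2018, then 0.629, 0.374,
0.082) the fit reproduces the published carrying capacity (posterior mean
within a few percent of 1.38 million) and, under the escapement ordering,
the published collapse behaviour under heavy harvest (2030 medians on the
10¹ scale for rates in 0.701–0.900). It does **not** reproduce the
published `r_max` (posterior mean ≈ 0.93 vs 1.32): the 2018→2019 crash
from ~1.3 million to ~10⁵ is far deeper than one application of a 0.629
annual rate can explain under any single-step ordering, so the posterior
demands a large process SD (≈ 0.8, pinned at its prior ceiling) and pulls
`r_max` down. The original analysis evidently explained that crash through
the harvest term itself — plausibly by feeding in the logged monthly
removals (> 1.3 million animals), which are not published — leaving its
process noise small and its growth-rate posterior near the prior. The
inflated process SD also widens and upward-biases this package's
no-harvest forecast means relative to the published ones (lognormal noise
raises ensemble means by `exp(sigma^2/2)` per year until density
dependence bites). Users with actual harvest *totals* should supply them
(`HarvestSchedule.from_totals`); rates are the published fallback.

## Numerical choices and limitations

- Abundances are reals internally; whole-animal rounding only at reporting
  boundaries.
- Quantile summaries use linear-interpolation percentiles; `h_msy` and
  other derived quantities are transformed per draw, never per summary.
- Ensemble medians for collapse scenarios sit near zero, so their
  Monte-Carlo stability is assessed on an absolute scale (thousands of
  animals), not relatively.
- One-year time step, August to August; no age structure, no Allee effect,
  no theta-logistic shape parameter, no time-varying `K`.
- The two printed rates touching the 2018→2019 interval (0.629 and 0.568)
  are not combinable from the published record; 0.629 is the default and
  0.568 is available via `datasets.load_harvest(alt_2018_rate=True)`.
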