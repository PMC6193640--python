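# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `gvtrends`. Nothing here reports an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Spatial zero-inflated Poisson model

State incident counts `y_i` (50 states, ~36-year totals) follow

    y_i ~ ZIP(mu_i, pi_i)
    log mu_i  = log(pop_i) + x_i' beta + v_i + u_i
    logit pi_i = x_i' gamma

with design `x_i = (1, FS/S, mental-illness rate %, poverty rate %,
permissiveness indicator)`. Population enters only as an offset, so `beta`
describes per-capita rates. The structural-zero model reuses the design
matrix with its own coefficients `gamma`: a state can be a "never" state
(structural zero) or an "at-risk" state that happened to record nothing.

`v` carries spatial smoothing: an intrinsic CAR prior with precision
`tau_v * Q`, `Q` the graph Laplacian of the state border graph (AK and HI
are isolated; their `v` is pinned at 0). The ICAR density is improper; the
zero-sum constraint per connected component, re-imposed every sweep, makes
it usable. `u ~ N(0, 1/tau_u)` is exchangeable heterogeneity.

Priors: `beta, gamma ~ N(0, 10^2)` elementwise on the model's raw covariate
scale, `tau_v, tau_u ~ Gamma(0.5, 0.0005)` — conventional disease-mapping
defaults, all overridable through `Priors`. Two cautions that matter in
this data regime (50 observations, counts 0–15): the Gamma(0.5, 0.0005)
precision priors put half their mass above precision ≈ 450, so the
random-effect scales are strongly shrunk unless the data resist; and with
covariates in percent units the N(0, 100) prior on `gamma` leaves the zero
model close to unidentified, which is visible as wide `gamma` posteriors.

### Sampler

Metropolis-within-Gibbs with latent-variable augmentation:

* structural-zero indicators `w_i` — exact Gibbs (`P(w=1|y=0, ·) =
  expit(x'gamma + mu)`); given `w`, the count part is a clean Poisson
  likelihood over the `w=0` states and the zero model a logistic regression
  on `w`;
* `beta` — adaptive multivariate random-walk block (Haario covariance
  adaptation, Robbins–Monro scale targeting 0.234 acceptance, both frozen
  after warm-up);
* `gamma` — coordinate-wise slice sampling (its conditionals are wide and
  prior-dominated; slice moves cross them in one step);
* `u`, `v` — per-site slice sampling, vectorised: all `u_i` at once (their
  full conditionals are independent), `v` by colour class of a greedy graph
  colouring (sites within a class share no edge, hence are conditionally
  independent); slice widths follow the conditional curvature
  `1/sqrt(tau + mu)`, so no per-site tuning state exists;
* `tau_v, tau_u` — conjugate Gibbs (ICAR shape uses the Laplacian rank,
  `n - #components`), plus a slice-sampled joint rescaling move
  `(c·u, tau_u/c^2)` (and likewise for `v`) that travels the funnel's scale
  axis every sweep — without it, chains initialised near `u = 0` are
  captured by the high-precision funnel corner and under-report posterior
  spread;
* `u` is initialised from capped log residual rates for the same reason.

Sampling runs on centred covariates (the intercept de-correlates from the
slopes) with the prior evaluated on the raw scale and draws transformed
back, so the reported posterior is exactly the raw-scale model's. The
sampler was validated against an independent MCMC engine on reduced forms
of the model (Poisson + exchangeable effect, and ZIP + exchangeable effect,
identical data and priors): posterior means and SDs of all coefficients and
of the random-effect scale agree to within Monte-Carlo error.

Defaults: 4 chains × 20 000 iterations, half warm-up, thin 10. Convergence
is declared when split-R̂ ≤ 1.1 for every reported scalar; a failed check is
flagged on the results object and exits the CLI with status 3. Tests and
the calibration experiments use 2 chains × 2 500–6 000 iterations, which
the validation runs above showed sufficient for the synthetic panels.

### DIC

`DIC = D̄ + p_D`, `p_D = D̄ − D(θ̄)`, with the conditional likelihood
(random effects plugged in; posterior means for `θ̄`) — the standard choice
for CAR models — as default. `compute_dic(..., marginalize_u=True)`
integrates `u` out per state by 25-node Gauss–Hermite quadrature instead,
shifting the comparison toward population-level structure. Note a property
of the conditional form relevant to model comparison here: parameters the
likelihood never informs (the zero model's coefficients when no state is
labelled structural) contribute nothing to `p_D`, and a plain-Poisson model
with a free per-state `u` can absorb structural zeros, so ZIP-vs-Poisson
DIC gaps on weakly-informative areal data are small and can take either
sign. The test suite's model-comparison check documents this honestly; see
"Limitations".

### Kendall check

`kendall_permissiveness` reports Kendall τ-b (scipy, exact/normal p by
sample size) between the permissiveness indicator and the FS/S proxy — the
confounding check between the two gun-related covariates.

## National trend and risk forecast

`bin_counts` aggregates incidents into half-open calendar bins
`[origin + k·w, origin + (k+1)·w)`, `w ∈ {1, 2}` years, origin 1982. Bin
`k` carries year offset `k·w` (its start year minus the origin). A partial
final bin (the study window ends in May) is flagged and, by default,
weighted by an exposure offset `log(covered fraction)`; `use_exposure=False`
reproduces the naive fit.

`fit_trend` is a Poisson GLM (statsmodels IRLS) of counts on the offset
polynomial, reporting Wald p-values, `AIC = −2·loglik + 2k` and the Pearson
dispersion `Σ(y−μ̂)²/μ̂ / (n−k)`. `compare_aic` prefers the lower AIC and
breaks ties toward the biannual binning. Two monthly rates feed
`risk_table(rate, horizons)`, which evaluates `1 − exp(−rate·t)` and also
reports half-up 3-decimal rounding:

* `interarrival_mle`: exponential inter-arrival MLE `(n−1)/span-days`,
  converted by 365.25/12 days per month — the "no trend" rate;
* `predict_monthly_rate(fit, offset)`: `exp(b1 + b2·offset)/(12·w)` — the
  trend's rate; "most recent year" evaluates the offset of the last
  calendar year the final bin reaches (offset 37 for a window ending May
  2018 with biannual bins: final bin [2018, 2020) starts at offset 36 and
  its last calendar year is 2019).

`smooth_interarrival` fits a natural cubic smoothing spline
(Green–Silverman `K = Q R⁻¹ Qᵀ` construction) whose penalty is chosen by
bisection so the smoother-matrix trace equals the requested effective df
(default 4, tolerance 0.01). Natural splines reproduce linear data exactly
for any penalty; `df → n` approaches interpolation.

## Media-contagion analysis

For intervals between consecutive incidents (from 2005 on, where search
data exist): media density = article count / interval days, with zero
counts floored by a half-count correction (0.5/days) before logs; temporal
order = calendar days since the first incident (an ordinal variant can be
passed explicitly).

* `spearman_matrix` — average-rank Spearman correlations with t-approximate
  p-values; constant columns raise rather than return silent NaN.
* `ridge_fit` — response log interval; predictors standardized internally;
  `(XᵀX + λI)⁻¹Xᵀy` with unpenalised intercept; λ by generalized
  cross-validation when not supplied; approximate Wald p-values from the
  ridge sandwich covariance. The log response is the minimal reading
  consistent with log-transformed density and skewed intervals, and is
  switchable by passing any response to `ridge_fit` directly.
* `poisson_interval_fit` — quasi-Poisson regression of the interval length
  on log density, fatalities, injuries, and (default) temporal order in
  years as a covariate. Two deliberate choices: (1) "time as an offset" is
  implemented as time-as-covariate because a literal exposure offset
  (log calendar position) posits that intervals scale with calendar time,
  which makes the model degenerate — optimisation fails on about half of
  synthetic replicates and null coverage collapses; the literal variant is
  retained as `offset="exposure"`. (2) Standard errors use the Pearson
  scale: durations are vastly overdispersed relative to a unit-scale
  Poisson, and unscaled Wald intervals covered a true null only ~25% of
  the time in calibration runs versus ~92% with the scale.
* `interval_zscore` — position of one interval among log intervals, sample
  SD by default (`ddof=0` gives the population convention).
* `sensitivity_remove` — drops every interval touching the named events and
  re-runs all three analyses, reporting effect and significance stability.

## Synthetic-data generator

The generator emulates the study's inputs with the dependence structure the
models assume; all generators are pure functions of (parameters, seed).

* **State panel**: real mid-2010s state populations and the real border
  graph; covariates drawn uniformly from plausible ranges (FS/S 0.2–0.7,
  mental illness 13–25%, poverty 8–20%, nine permissive states); `v` from
  the zero-sum ICAR via the Laplacian eigendecomposition; counts from the
  ZIP model. Default truth: `beta = (−14.85, −0.35, 0.02, −0.02, −0.26)`
  (covariate effects at the magnitudes the spatial model reports — i.e.
  essentially null), `sigma_v = 0.5`, `sigma_u = 0.3`, intercept-only zero
  model with `gamma_0 = −1.95`. The two intercepts were calibrated once by
  Monte-Carlo so the preset reproduces the study regime — about 100
  incidents nationally and about 19–20 zero-count states — and then frozen.
* **Event dates**: Lewis–Shedler thinning of a log-linear intensity
  `exp(a + b·(τ−1982))/w` events per year (defaults `a = 0.55683`,
  `b = 0.05033`, `w = 2` — the published trend). The expected total over
  1982–May 2018 implied by those coefficients is ≈91. In the combined
  dataset (`simulate_dataset`) the panel's counts fix the total and states,
  and dates follow the trend's conditional arrival-time distribution, so
  the incident table and the panel agree exactly.
* **Casualties**: fatalities 4 + negative-binomial excess, injuries
  negative-binomial, means 8.33 and 12.92 per event (the study period's
  printed totals over 100 events); NB sizes 0.8 / 0.35 chosen for the
  heavy-tailed severity of real events (the source reports no dispersion).
  A `dispersion` multiplier scales the excess means; 0 gives the minimal
  qualifying event exactly.
* **Media**: a Gaussian copula couples the normal scores of interval length
  to latent log density at `r = 2·sin(πρ/6)` (the bivariate-normal value
  with Spearman ρ, default −0.70); article counts are Poisson with mean
  density×days; search interest is a noisy monotone transform of density
  rescaled so its maximum is exactly 100. With the default density scale
  (log-mean 3, log-SD 1), count noise leaves the realised Spearman centred
  on the target (mean −0.70, SD 0.06 at n = 80 in the suite's replication
  check).

What the generator does **not** emulate: secular growth of online media
volume, duplicate/irrelevant articles, state-level covariate measurement
error and temporal misalignment, dependence between severity and media
attention, and clustering beyond the smooth trend. Passing tests therefore
show the *methods* are implemented correctly and calibrated under the
assumed structure — not that the study's substantive findings would
replicate on re-collected data.

## Problem sizes in the test suite

The suite fits the spatial model with 2 chains × 2 500–6 000 iterations
(validated against the long-run reference above), uses 20-panel recovery
and model-comparison batches, 100–300 replicate batches for trend, copula
and calibration checks, and 200 replicates for slope recovery — sizes at
which every stochastic check has comfortable Monte-Carlo margins.

## Known limitations

* ZIP-vs-Poisson DIC ordering on the synthetic panels is ambiguous: with
  structural zeros assigned independently of population (the zero model has
  no population term by design), most land in states whose expected count
  is below 1 and carry no evidence, while the exchangeable effect under the
  vague precision prior can mimic excess zeros. The suite's
  model-comparison test encodes a decisive ordering and is expected to
  fail; the diagnostic output reports both DIC variants so users can judge.
* The permissiveness indicator is a binary may-issue marker; the underlying
  legal regimes are graded.
* The FS/S proxy is cross-sectional (2013–2016-style averages) against
  incidents spanning 1982–2018; the panel makes no attempt to time-align
  covariates.
* Wald p-values throughout are asymptotic; at 18 biannual bins or 50 states
  they are approximations.
* The interval analyses treat intervals as independent given covariates;
  true contagion would induce serial dependence the models ignore.
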