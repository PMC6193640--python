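# gvtrends

Statistical models for the incidence of U.S. mass shootings — events with at
least four victim fatalities (perpetrator excluded) — addressed to
epidemiologists and quantitative social scientists who want to ask three
questions of an incident series:

1. **Where?** Do state-level factors (household gun ownership proxied by the
   firearm-suicide fraction FS/S, serious-mental-illness rate, poverty rate,
   gun-law permissiveness) predict state incident counts?
2. **When?** Is the national incidence rate rising, and what is the
   probability of another event within the next few months?
3. **Why so soon?** Does heavier online media coverage after one shooting
   predict a shorter wait until the next?

## Models

**Spatial count model** (`SpatialZIPModel`). State counts follow a
zero-inflated Poisson with a population offset,

```
y_i ~ ZIP(mu_i, pi_i)
log mu_i  = log(pop_i) + x_i'beta + v_i + u_i
logit pi_i = x_i'gamma
```

where `v` is an intrinsic CAR (ICAR) field over the state border graph —
each state shrunk toward its neighbours, zero-sum per connected component —
and `u` is an exchangeable normal effect. Inference is MCMC (latent
structural-zero augmentation, adaptive Metropolis blocks, slice sampling for
the random effects and the zero model, conjugate Gibbs for precisions), with
split-R̂ diagnostics and DIC model comparison against the plain spatial
Poisson variant.

**National trend** (`NHPPTrendModel`). Counts in one- or two-year calendar
bins follow a Poisson regression `log E[count] = b1 + b2·t` with `t` years
since 1982 (optional quadratic term; AIC comparison across bin widths;
Pearson overdispersion). Two monthly rates feed the analytic risk forecast
`P(event within t months) = 1 − exp(−λ·t)`: the homogeneous inter-arrival
MLE `λ = (n−1)/span`, and the trend's prediction for the most recent year,
`exp(b1 + b2·t_last)/24`. A natural cubic smoothing spline with fixed
effective degrees of freedom (`smooth_interarrival`) visualises the
shrinking gaps between events.

**Media contagion** (`MediaContagionModel`). For each inter-incident
interval, media coverage density (articles per day) and relative search
interest are tested against the interval length by a Spearman matrix, a
ridge regression of log interval on standardized log density and temporal
order (GCV-chosen penalty; density and time are collinear), and a
quasi-Poisson regression of the interval on log density adjusting for the
opening event's casualties and calendar time, with an outlier-removal
sensitivity re-run.

A calibrated synthetic-data generator (`gvtrends.simulate`) emulates all
inputs — ZIP/ICAR state counts over the real U.S. border graph, event dates
from a log-linear-intensity Poisson process by thinning, overdispersed
casualty marks, and media covariates coupled to the following interval
through a Gaussian copula — so the whole pipeline is testable end to end
without the study's compiled dataset.

## Worked example

```python
import numpy as np
from gvtrends import (SpatialZIPModel, NHPPTrendModel, interarrival_mle,
                      risk_table, simulate_state_panel, simulate_nhpp_events)

panel, truth = simulate_state_panel(seed=42)        # 50 states, US borders
fit = SpatialZIPModel(panel).fit(n_chains=2, n_iter=6000, seed=1)
print(fit.summary().round(2).iloc[:5])

dates = simulate_nhpp_events(0.55683, 0.05033, 1982.0, 2018.37, seed=3)
trend = NHPPTrendModel(dates, width_years=2).fit()
lam_m = trend.predict_monthly_rate(trend.most_recent_year_offset)
print(f"slope {trend.slope:.4f} (p={trend.slope_p_value:.2g}), "
      f"recent monthly rate {lam_m:.3f}")
print(risk_table(lam_m, [1, 3, 6]).table)
```

prints:

```
                              Mean    SD   2.5%  Median  97.5%
Intercept                   -12.63  1.44 -15.23  -12.61  -9.80
FS/S                          1.09  1.25  -1.38    1.11   3.51
Serious mental illness rate  -0.11  0.07  -0.25   -0.11   0.03
Poverty rate                 -0.10  0.06  -0.24   -0.09   0.01
Gun law permissiveness        0.42  0.52  -0.52    0.41   1.51
slope 0.0596 (p=1.9e-06), recent monthly rate 0.445
   months  probability  probability_3dp
0     1.0     0.359227            0.359
1     3.0     0.736905            0.737
2     6.0     0.930781            0.931
```

The posterior table reads like the study's state-level summary: every 95%
interval brackets zero, i.e. none of the four covariates predicts the
state incident rate on these data. The positive slope says the two-year
counts have grown ~6% per year; the forecast column turns the most recent
year's monthly rate into the probability of at least one further event
within 1, 3 and 6 months.

The same stages run from the shell:

```sh
gvtrends run-all --outdir runs/demo --seed 42
gvtrends forecast --outdir runs/fc --rate 0.227 --rate 0.468 \
    --horizon 1 --horizon 2 --horizon 3 --horizon 6 --horizon 9 --horizon 12
```

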