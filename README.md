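# gnhswitch

Regime-switching analysis of a daily well-being index.

Social-media-derived mood indices — such as the Gross National Happiness
(GNH) index, a 0–10 daily sentiment score for a country — tend not to drift
smoothly but to jump between persistent *regimes*: stretches of "happy"
days and stretches of "unhappy" days, with the switches triggered by
events such as lockdown announcements. `gnhswitch` packages the full
analysis chain for such a series, aimed at researchers in well-being
economics and population-mental-health surveillance:

* **Synthetic data** with the assumed statistical structure (a two-state
  Gaussian Markov regime process plus a weekly cycle, and a pandemic
  covariate generator), so the whole pipeline is testable without access
  to a proprietary index.
* **Preprocessing**: removal of the average day-of-week effect, cubic
  spline imputation of weekly administrative data to a daily grid, a PCA
  "lack of mobility" index from the six community-mobility categories,
  log transforms and lags.
* **Diagnostics** that motivate a non-linear model: supremum-Wald
  structural break test with unknown break date (parametric bootstrap
  p-value), the McLeod–Li ARCH LM test, and the Phillips–Perron unit-root
  test with interpolated Dickey–Fuller critical values.
* **The core model**, a two-state Markov-switching dynamic regression
  (MSDR): Hamilton filter, Kim smoother, EM estimation, robust sandwich
  standard errors, expected regime durations and one-step-ahead state
  predictions.
* **A probit model** of the probability of being in the happy state as a
  function of pandemic covariates, with Huber–White standard errors.

## The model

The observed index on day *t* is

```
y_t = μ_{s_t} + e_t,     e_t ~ N(0, σ_{s_t}²),
```

where the latent state `s_t ∈ {unhappy, happy}` follows a first-order
ergodic Markov chain with transition matrix `P`, `P_ij = Pr(s_t = j | s_{t-1}
= i)`. Both the level μ and the volatility σ switch with the state, and the
level adjusts *immediately* after a switch (dynamic, not autoregressive,
switching). The initial state distribution is tied to the stationary
distribution of `P`, so the two-state model has exactly six free
parameters: two means, two volatilities, two persistence probabilities.
Expected regime duration is `D_i = 1 / (1 − P_ii)` days. The follow-up
question — *which* conditions make a happy day more likely — is a probit:

```
Pr(y_t ≥ c) = Φ(α₀ + α₂' X_t),
```

with `c` the full-sample mean of the smoothed index and `X_t` the pandemic
covariates (lagged cases, border arrivals, jobseeker payments, lack of
mobility).

## Worked example

```python
from gnhswitch import nz_parameters, simulate_regime_series, fit_msdr

sim = simulate_regime_series(nz_parameters(), T=548, seed=3)
fit = fit_msdr(sim.to_daily_series("gnh"), seed=3)
print(fit.summary())
```

```
Markov-switching dynamic regression, 2 states, T=548
log-likelihood 164.176  AIC -316.35  BIC -290.52  (14 EM iterations, converged)
   unhappy: mean 6.9650 (0.0105)  sigma 0.1785 (0.0069)  p_stay 0.9802 (0.0081)  duration 50.59 days
     happy: mean 7.3181 (0.0110)  sigma 0.1398 (0.0084)  p_stay 0.9638 (0.0161)  duration 27.66 days
```

The fit recovers the generating regime structure from 548 days: an
unhappy state near 6.97 with higher volatility, a happy state near 7.30
with lower volatility, both highly persistent (a day in a state is
followed by the same state with probability ≈ 0.96–0.98), giving expected
sojourns of weeks. Robust standard errors are in parentheses. The
`examples/` directory holds one short script per capability (simulation,
diagnostics, switching fit, probit, full pipeline), each printing and
explaining its numbers; the `gnhswitch` CLI exposes the same steps as
`simulate`, `preprocess`, `diagnose`, `fit`, `predict-states`, `probit`
and `run` subcommands.

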