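# Methods

## The switching model and its estimation

The observation model is a Gaussian mixture driven by a hidden first-order
Markov chain: `y_t = μ_{s_t} + e_t`, `e_t ~ N(0, σ_{s_t}²)`. We deliberately
use *dynamic* switching (no autoregressive carry-over): after the chain
changes state, the level of the index adjusts within the day. That suits a
high-frequency mood score, which reacts to announcements rather than
reverting gradually. The chain is assumed ergodic; nothing in the data
identifies the state on day one separately, so the initial distribution π
is tied to the stationary distribution of the transition matrix `P` rather
than estimated freely. A two-state fit therefore has six free parameters
(μ₁, μ₂, σ₁, σ₂, P₁₁, P₂₂), the count the duration and persistence
interpretation rests on.

**Filtering.** The Hamilton filter computes `ξ_{t|t-1} = Pᵀ ξ_{t-1|t-1}`
and updates by elementwise multiplication with the state densities
followed by renormalisation; the log-likelihood is the sum of the log
normalisers. Densities are evaluated in log space and max-shifted before
exponentiation, so the filter survives observations far in the tails; if
every state's density underflows to exact zero the filter raises an error
naming the observation. The Kim smoother runs the standard backward
recursion `ξ_{t|T} = ξ_{t|t} ⊙ [P (ξ_{t+1|T} ⊘ ξ_{t+1|t})]`, with each row
renormalised to absorb float drift. Both recursions are compiled with
numba; filter, smoother and log-likelihood agree with exhaustive path
enumeration to 1e-10 for short series (tested).

**EM.** The E-step is filter + smoother plus pairwise smoothed transition
probabilities; the M-step has closed forms (smoothed-weighted means and
variances; expected transition counts normalised by expected visits). π
is reset to the stationary distribution of the updated `P` at each
iteration. Because π is a function of `P` rather than a free parameter,
this closed-form update is a *generalised* EM: it maximises the expected
complete-data likelihood up to the O(1) initial-state term and can, on
weakly separated data, overshoot by a sliver near a fixed point. The loop
therefore guards ascent directly: an update that lowers the tied
likelihood is rejected and the iteration stops at the previous (ascent)
point, so the recorded likelihood trace is monotone by construction.

Defaults: convergence when the relative likelihood gain falls below 1e-8,
cap of 1000 iterations (non-convergence is reported, not raised); 5
starts — state means at the 25th/75th sample percentiles with a common
sigma and persistence 0.9, plus 4 seeded perturbations — with the best
final likelihood kept; sigmas floored at 1e-6 of the sample SD against
degenerate collapse; a state whose total smoothed weight falls below one
observation-equivalent aborts that start. States are relabelled so means
ascend; with two states the labels are "unhappy" and "happy". Ties in the
day classification go to the happier state.

**Inference.** Robust standard errors use the sandwich `H⁻¹ S H⁻¹` on a
working parameterisation (means, log σ, logit persistence, π tied as
above): `H` is the numerical observed information (central second
differences, step 1e-5·(1+|θ|)) and `S` the outer product of
per-observation numerical score contributions. SEs map back to the
natural scale by the delta method (σ·se(log σ); p(1−p)·se(logit p)). A
singular or near-singular information matrix (condition number above
1e12, e.g. identical states) raises an error. Duration standard errors
are delta-method transforms se(D) = se(p)/(1−p)²; this is a different
estimator from anything whose derivation is unstated elsewhere, and is
labelled as such. The sandwich SEs agree with a 50-replicate parametric
bootstrap within 30% (tested) and with the iid approximation
σ/√(Tπ) within a factor 1.5.

Model choice uses AIC = −2ℓ + 2k and BIC = −2ℓ + k ln T; a two-state fit
beats a single Gaussian by BIC in ≥95% of simulated regime series
(tested).

## Diagnostics

*Sup-Wald break.* The break regression is a mean shift only (constant
plus post-break indicator) — the natural counterpart of a model whose
mean switches on a constant. For each candidate break day in the
trim-fraction (default 0.15) interior we compute the Wald statistic with
the HC0-robust variance, which for group dummies reduces to cumulative
sums and lets the whole scan and the bootstrap run vectorised. The
p-value is a parametric bootstrap under the Gaussian no-break null
(default 999 replicates, add-one rule). The statistic is exactly
location-scale invariant, so the bootstrap is exact under Gaussianity up
to Monte-Carlo error; asymptotic critical-value approximations are
deliberately not implemented.

*McLeod–Li / ARCH LM.* Squares of the demeaned series regressed on their
own first q lags, for q = 1..5 by default; both the joint F statistic and
T·R² against χ²(q) are reported. Matches the standard ARCH LM
implementation in statsmodels to 1e-9 (tested).

*Phillips–Perron.* First-order autoregression with constant (and
optionally trend), with Bartlett long-run variance correction at
truncation floor(4·(T/100)^(2/9)) when not given. Both the
normalised-bias statistic Z_ρ and the studentised Z_t are reported —
published tables in this literature do not always name the variant, and
the two have very different scales — against Dickey–Fuller critical
values interpolated in sample size from the classical tables. At zero
lags Z_t reduces exactly to the Dickey–Fuller t statistic (tested against
statsmodels' adfuller). Critical-value signs follow the standard
convention (all negative).

*Variance comparison.* Two-sided F ratio of within-state sample variances
of the classified days, F(n₁−1, n₂−1).

All four tests hold 5% nominal size within [0.03, 0.07] in null
simulations (≥200–500 replicates, tested).

## Probit

Maximum likelihood by Newton–Raphson on the exact observed Hessian with
step-halving; convergence when the gradient max-norm falls below 1e-8.
The optimisation runs on an internally standardised design — the
covariates span five orders of magnitude, and probit estimates are
affine-equivariant, so estimates and covariances are mapped back to the
raw scale exactly. Divergence with step-halving exhausted, or a diverging
linear index with a non-vanishing gradient, raises a separation error
naming the offending covariate. Robust SEs are the Huber–White sandwich.
The default happy/unhappy threshold is the full-sample mean of the
smoothed series, recomputed from the data rather than hard-coded (≈7.13
on the reference window). Covariates enter on the scales implied by the
reference coefficient magnitudes: lagged raw cases, raw border arrivals,
raw jobseeker payments, and the PCA mobility index; the set is
configurable. Marginal effects are out of scope.

## What the synthetic generator emulates — and what it does not

The generator reproduces the *assumed statistical structure* of the study
conditions:

* Two-state Gaussian regime process with means 6.966/7.301, sigmas
  0.176/0.142, persistences 0.966/0.967, started from the stationary
  distribution; ~548-day default span (the study window), 5,480 days for
  recovery experiments.
* An additive weekly cycle, Monday low (−0.35) to Friday high (+0.35),
  sized so removing it shrinks the raw SD from ≈0.30 to ≈0.19 — the
  contrast reported between the raw and smoothed index. The exact weekday
  profile is otherwise unpublished; only its zero sum matters downstream.
* Probit covariates with the reference locations and scales: daily cases
  ~ N(13.11, 22.7²) truncated below 0; mobility index ~ N(−0.99, 1.61²);
  border arrivals exponentiated from N(5.20, 1²) truncated above at 9.44
  on the log scale (the reported log-scale maximum; the truncation also
  prevents quasi-separation from extreme draws); jobseeker payments
  exponentiated from N(11.96, 0.10²). The reported log-scale SD for
  jobseeker payments (0.93) exceeds its own printed min–max range
  (11.87–12.14) and is internally impossible; 0.10, consistent with that
  range, is used instead. Slopes are the reference coefficients; the
  intercept is balanced to the negative mean slope contribution so
  prevalence ≈ 0.5.

It does **not** emulate: sentiment scoring of the underlying text stream,
serial correlation *within* a regime, calendar covariation between the
index and the covariates (covariates are drawn independently of the
regime path), or holiday effects. Passing recovery tests therefore shows
the estimators are correct for the assumed data-generating process, not
that the process is a complete description of real social-media indices.

## Numerical and design choices

* One integer seed drives everything; components derive sub-streams by
  fixed offsets. Simulation uses inverse-CDF draws from a single uniform
  stream so state paths are reproducible across platforms.
* The day-of-week adjustment is additive and estimated once on the full
  sample ("average day-of-week effect"), not rolling; it is exactly
  idempotent on whole-week spans.
* Weekly-to-daily imputation uses the natural cubic spline (zero second
  derivative at the ends) and requires ≥4 anchors; it matches an
  independent tridiagonal solve to 1e-8 (tested).
* The mobility PCA standardises columns (correlation-matrix PCA) because
  the six categories are incommensurate percent changes, and orients the
  component to correlate positively with the residential column, so
  higher = less mobility.
* Count covariates use log(1+x) so zero-count days map to zero on the log
  scale.
* Case-count lag defaults to one day; "lagged" is otherwise unspecified
  in the reference analysis.
* Expected-duration point estimates use D = 1/(1−p_stay) only. At the
  reference persistence 0.966 this gives 29.4 days; a printed table value
  of 31.00 is consistent with an unrounded persistence estimate, and a
  prose figure of 48.67 days is irreconcilable with the same table — the
  package reports the formula value and nothing else.
* Recovery experiments in the tests and the acceptance script use one
  series of 5,480 days (ten times the study window) for the switching
  model and 100,000 observations for the probit; these sizes make
  Monte-Carlo error comfortably smaller than the reporting precision of
  the reference estimates while keeping a full run in seconds.

## Known limitations

* Robust sandwich SEs are implemented for the two-state model (the
  general S-state filter/EM machinery works, but the working
  parameterisation and delta maps are two-state).
* The sup-Wald bootstrap assumes Gaussian innovations under the null;
  heavy-tailed nulls will distort its size.
* The Phillips–Perron critical values are interpolated from classical
  finite-sample tables, not response-surface regressions; differences are
  in the second decimal.
* The probit assumes independent observations; with strongly
  autocorrelated daily outcomes its sandwich SEs understate uncertainty.
  The reference analysis makes the same assumption.
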