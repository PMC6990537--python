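# Methods

This note records the statistical models implemented in `crfpm`, the
numerical choices behind the fits, what the simulators do and do not
emulate, and the design decisions taken where more than one reasonable
convention exists.

## Data model

A competing-risks cohort is one row per subject: a positive follow-up
time `T` (the minimum of the true first-event time and the censoring
time), an event code `0..K` (0 = censored, 1..K = cause of the first
event), and a numeric covariate matrix. Event code 0 is reserved for
censoring (the Stata convention, for interoperability). Times are
treated as exact and continuous; ties are allowed and handled downstream
(Breslow in the partial likelihood). Categorical covariates are expanded
to indicator columns at read time, reference level = first declared
category, so every model sees a plain design matrix. Only complete-case
analysis is supported: rows with missing covariates are dropped by
`complete_cases`, which reports the count. An optional preprocessing
step administratively censors follow-up beyond a cap (e.g. 15 years:
`time > cap ⇒ (cap, event = 0)`). The package assumes the time origin
(e.g. a seroconversion midpoint) has been applied upstream.

## Spline basis

All baselines are natural cubic splines in `ln t` in the restricted
cubic parameterization: with boundary knots `k_min < k_max` and internal
knots `k_j`,

```
v_1(x) = x
v_{j+1}(x) = (x − k_j)³₊ − λ_j (x − k_min)³₊ − (1 − λ_j)(x − k_max)³₊,
λ_j = (k_max − k_j)/(k_max − k_min).
```

The cubic terms cancel outside the boundary, so the basis is exactly
linear there, and with no internal knots the model is linear in `ln t`
— i.e. Weibull — which the test suite exploits as an exact reduction.
"Degrees of freedom" follows the stpm2/rstpm2 convention
`df = #internal knots + 1` (excluding the intercept). Knots are placed
per cause: boundary at the log of the first and last event times of
that cause, internal knots at equally spaced centiles of its log event
times (df = 3 → 33.3rd and 66.7th). Heavily tied event times can make
centile knots collide; this raises a degenerate-knots error rather than
silently merging knots. No basis orthogonalization is applied: with
analytic-Hessian Newton polishing the raw basis converges tightly on
all study designs, and keeping the raw scale means coefficients need no
back-transformation.

## Likelihood engine

Every flexible parametric fit maximizes a likelihood of the form

```
ℓ(θ) = Σ_events [ η_i + ln(dη_i/d ln t) − ln t_i ]
     − Σ_rows w_i (H(t_stop,i) − H(t_start,i)),       H = exp(η), η = Zθ
```

over at-risk segments `(t_start, t_stop]`. Plain fits have
`t_start = 0, w = 1`; the censoring-weighted subdistribution route
supplies post-competing-event segments whose weight multiplies only the
cumulative-hazard increment (event rows always carry weight 1, so the
event term is unweighted — this makes the no-competing-events reduction
to the plain fit exact). Gradient and Hessian are analytic; the
covariance is the inverse observed information at the optimum.

Numerical choices:

* **Optimization.** Damped Newton with the analytic Hessian straight
  from an exponential-hazard start (`γ_0 = ln(events/exposure)`, unit
  slope); BFGS warm starts with up to three jittered restarts as
  fallback. Convergence: max |gradient| below `1e-6 · max(1, 1e-3 |ℓ|)`.
  The |ℓ|-scaling matters: likelihood sums over 10⁵–10⁶ rows carry
  ~`1e-16·|ℓ|` float rounding noise, so absolute `1e-12` line-search
  comparisons would stall.
* **Hazard positivity.** A log-cumulative-hazard model does not force
  `dη/d ln t > 0`. Below a floor of `1e-8` the `ln(slope)` event term is
  replaced by its tangent line, which keeps the objective finite with an
  uphill gradient back into the feasible region; a fit that ends with
  the floor active is reported as non-converged.
* **CIF integration (cause-specific route).** `F_k = ∫ h_k S` is
  computed by composite Simpson on a grid uniform in `ln t` (2048 points
  by default, augmented with the requested times), extended downward
  until the total cumulative hazard is below 1e-12 so the truncated mass
  is negligible. The conservation identity `Σ_k F_k + S = 1` is checked
  at every requested time at tolerance 1e-6 and violations raise.
* **Confidence bands.** Delta method on the `ln H` scale (a linear
  function of the parameters), back-transformed through
  `F = 1 − exp(−H)`, which keeps bands inside [0, 1]. For the
  cause-specific-route CIF, the parameter gradient of the integral is
  taken by central finite differences per cause and combined with the
  block-diagonal covariance of the separate fits, with the variance
  propagated on the `ln(−ln(1−F))` scale.

## Cause-specific models

One fit per cause, competing events censored at their occurrence. The
stacked (Lunn–McNeil) variant duplicates each subject once per cause
with separate spline baselines (per-cause knots, placed on each cause's
own event times — pooled-knot stacking is not used) and maximizes one
joint likelihood; covariates listed as *shared* get a single coefficient
across causes. With no shared effects the joint problem is block
diagonal, so estimates equal the separate fits — an equivalence the test
suite checks to 1e-5.

## Subdistribution models

**Weighted route.** The censoring survival `G(t|x) = exp(−H_c(t|x))` is
estimated by a flexible parametric fit with the censoring indicator as
the event (df = 3 by default, on the full covariate set; a marginal
covariate-free `G` is available for classic Fine–Gray-style weights).
Subjects with a competing event at `s` are expanded into intervals of
width δ (default 0.1 year) covering `(s, τ]`, τ the largest observed
event-of-interest time (later rows cannot enter any risk set), each
weighted by `G(t_stop|x)/G(s|x)` evaluated at the interval's right
endpoint (the conservative choice). Weights below 1e-12 are dropped with
a log notice. The expansion is deterministic. The same expansion feeds
the weighted flexible parametric fit and the Fine & Gray partial
likelihood; halving δ moves the estimates by well under 0.01 on the
benchmark designs, so coarse splits are adequate.

**Fine & Gray.** Weighted Cox partial likelihood on the expanded data,
Breslow ties, Newton iterations with risk sums computed by sorted
suffix-cumsums (O(n log n) per iteration). Standard errors are sandwich
estimates clustered on subject, since the expansion creates correlated
rows; the weighted Breslow estimator gives the baseline cumulative
subdistribution hazard. A post-convergence |β| > 15 is reported as
monotone likelihood (separation) naming the covariate.

**Direct route.** One joint likelihood over all causes,

```
ℓ = Σ_i [ Σ_k d_ik ln( h_k^sd(t_i) (1 − F_k(t_i)) )
        + (1 − Σ_k d_ik) ln( 1 − Σ_k F_k(t_i) ) ],
```

maximized by damped Newton with the exact analytic Hessian (quasi-Newton
methods crawl on this likelihood's ill-conditioned censored-term
valley). The likelihood requires `Σ_k F_k < 1` at censored
observations; iterates outside that region hit a tangent-line barrier,
and a fit with the constraint active at the optimum (margin < 1e-6) is
flagged as boundary-active with a warning. Initial values are per-cause
cause-specific fits with intercepts shifted down until the constraint
holds. Away from censored times nothing constrains `Σ_k F̂_k ≤ 1` in
either route; `check_cif_sum` reports (never clips) violations. The
direct route can fail to converge at small sample sizes; failures raise
with the optimizer trace rather than returning a bad fit.

A practical note on specification: if a competing cause's true
subdistribution is non-proportional (as in the classic simulation design
below, where the cause-2 subdistribution cannot be proportional when
cause 1's is), forcing a constant competing-cause effect in the direct
route biases the coefficient of interest through the shared censored
term. Giving the competing cause a covariate × `ln t` interaction
restores unbiasedness; the validation studies fit that specification.

## Inference

AIC/BIC model selection over a df range (default 1..5, AIC, lowest
wins; non-converging candidates are excluded with a notice), LR tests
(`2Δℓ` against chi-square with Δparams df; a full model with fewer
parameters or a worse likelihood beyond numerical slack raises), and
time-varying-effect tests by refitting with a covariate × time-basis
interaction (default `ln t`; full-spline optional). `n` in BIC is the
number of subjects, never expanded rows. For the weighted route these
statistics use the censoring-weighted pseudo-likelihood; they are
reported with that label and no exact chi-square calibration is claimed.
No multiple-testing adjustment is applied — tests are reported at a
flat 5% level. Stacked-risk summaries cumulate the per-cause CIFs in
declared cause order; the top band is the total first-event risk, which
equals `1 − S` on the cause-specific route by conservation.

## Simulators

* `simulate_csh`: per-cause Weibull cause-specific hazards
  `h_k = λ_k p_k t^{p_k−1} e^{xβ_k}`; the first event is the minimum of
  independent per-cause latent times, equivalent to drawing the time
  from the total hazard and the cause with probability `h_k/Σ_j h_j`.
  Censoring: exponential, uniform window, or administrative cap.
* `simulate_fine_gray`: the classic proportional subdistribution design
  `F₁(t|x) = 1 − [1 − p(1 − e^{−t})]^{exp(xβ₁)}` (unit-exponential base
  inside the CIF), cause-1 membership drawn with probability
  `F₁(∞|x) = 1 − (1−p)^{exp(xβ₁)}`, cause-1 times by inverse CDF,
  cause-2 times exponential conditional on non-membership. Defaults are
  the validation study conditions: `p = 0.3`, `β₁ = 0.5`, exponential
  censoring at rate 0.45, calibrated once to yield ≈30% censoring under
  those parameters.
* `simulate_macs_like`: a structural emulator of a three-cause HIV
  seroconverter cohort — AIDS, non-AIDS disease, unrelated death, plus
  loss to follow-up and a 15-year administrative cap — with covariate
  marginals matching the published cohort (recruitment period 1
  prevalence 0.862, age < 40 prevalence 0.7091, CD4 categories 0.0811 /
  0.1622 / 0.7568) and hazards chosen for an AIDS-dominant event mix.
  It matches marginal prevalences only: joint covariate structure,
  visit schedules, interval-censored origins and fitted effect sizes
  are deliberately not emulated, so tests against it validate structure
  and plumbing, not epidemiology. An optional missing-completely-at-
  random mask exercises the complete-case path.

Every generator takes one seed, uses one private `numpy` generator per
call, and is reproducible bit for bit. Because all generators draw from
idealized parametric truths, passing recovery tests demonstrates
correctness of the estimators under their own assumptions — not
robustness to the messiness of real cohort data (informative censoring,
measurement error, non-proportionality beyond the forms simulated).

## Validation studies and problem sizes

The test suite and `scripts/acceptance.py` run: the constant-hazard
closed-form CIF check (n = 50 000, fitted `F₁(1)` vs `(1 − e^{−2})/2`);
Weibull-reduction equivalence at n = 5000 against an independent Weibull
MLE (coefficients to 1e-4, log likelihood to 1e-6 relative);
subdistribution recovery over 100 replicates at n = 2000 (mean β̂ within
0.05 of 0.5; empirical SD within 25% of the mean model SE);
cross-method agreement on one n = 5000 draw (max pairwise |Δβ̂| < 0.05);
stacked/separate equivalence (1e-5); conservation (1e-6 at 200 grid
points) and the `F = 1 − exp(−H^sd)` identity (1e-12); split-width
insensitivity (δ = 0.1 vs 0.01, |Δβ̂| < 0.01); LR type-I error at
n = 1000 (500 replicates for a null covariate, 200 for a null
time-varying term, band 0.05 ± 0.02); and AIC selection consistency
(df = 1 chosen in ≥60% of 200 Weibull replicates). These sizes keep the
whole battery at a few minutes on one core while leaving Monte Carlo
error comfortably inside each tolerance.

## Known limitations

* Hazard-scale models only; odds and probit scales are out of scope.
* No delayed entry / left truncation in the public API (entry times
  exist only inside the weighted expansion).
* Weighted-route standard errors use the inverse observed information
  of the pseudo-likelihood (adequate in the validation studies; a
  clustered sandwich is provided only for the Fine & Gray comparator).
* No goodness-of-fit machinery for choosing between the two
  subdistribution routes.
* The direct route's CIF-sum constraint is enforced only where the
  likelihood requires it (censored observations); extrapolated sums can
  exceed 1 and are reported, not repaired.
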