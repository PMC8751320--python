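# Methods

## Model

`fvcjoint` implements a shared-parameter joint model for a longitudinal
lung-function marker and a time-to-first-event outcome in a two-arm
randomised trial of systemic sclerosis-associated interstitial lung
disease (SSc-ILD).

**Longitudinal sub-model.** FVC% predicted for subject *i* at time *t*
(years since randomisation) follows a Gaussian linear mixed model

y_i(t) = β₀ + β_ata·ATA_i + β_base·(FVC0_i − c) + (β_t + β_tx·arm_i)·t + u₀ᵢ + u₁ᵢ·t + ε,

with (u₀, u₁) ~ N(0, D) unstructured and ε ~ N(0, σ²).  ATA status
(anti-topoisomerase I antibody) and baseline FVC shift the level only;
the treatment arm enters through the slope, so β_tx is the
treatment-vs-control difference in the annual rate of FVC change.
Baseline FVC is centered at the sample mean c, which is stored with
every fit; only the intercept changes under a different centering.
The week-0 measurement is used as the baseline covariate and excluded
from the response vector (responses start at the week-2 visit).

**Event sub-model.** The hazard of the composite first event
(hospitalisation of a given category, or death) is piecewise
exponential with five internal knots by default, stratified by ATA
status: the two strata share knot locations but have separate piece
heights (12 baseline parameters at the default knot count).  Knots are
placed at the j/(n+1) empirical quantiles (linear interpolation) of the
observed uncensored event times pooled across strata; ties collapse
with a warning.  Intervals are half-open [t_j, t_{j+1}) and the final
piece extends indefinitely.

**Association.** With the primary *slope* structure the subject's hazard
is h_i(t) = h0_s(t)·exp(α·slope_i) where slope_i = β_t + β_tx·arm_i + u₁ᵢ
is the subject's annual FVC%-predicted slope; because trajectories are
linear the multiplier is constant in time and the cumulative hazard is
exp(α·slope_i)·Λ0_s(t).  With the secondary *current-value* structure
h_i(t) = h0_s(t)·exp(α·(m_i(t) − c)) with m_i(t) the error-free
trajectory, parameterised against FVC centered at c: this absorbs
exp(α·c) into the baseline heights (which then refer to a subject at
FVC = c) and removes the near-collinearity between α and the log
heights that otherwise stalls the optimiser; α and every hazard ratio
are unaffected.  Writing m̃_i(t) = A_i + C_i·t for the centered
trajectory, over each constant-hazard piece [a, b) the cumulative
hazard has the closed form
h0_j·e^{αA}(e^{αCb} − e^{αCa})/(αC), replaced by the
midpoint approximation h0_j·e^{αA + αC(a+b)/2}(b − a) when
|αC(b − a)| < 1e-8 (the two agree to machine precision at that scale).
Hazard ratios for a k-point *decrease* are exp(−k·α), so reported HRs
above 1 mean decline is harmful.

## Likelihood and quadrature

The marginal likelihood integrates the random effects out of the
product of the longitudinal density, the survival factor
h_i(T)^δ·exp(−Λ_i(T)) and the N(0, D) prior.  Because the longitudinal
factor is Gaussian, the integral is rewritten exactly as

f(y_i) · E[ f_surv(b) | y_i ],  with  b | y_i ~ N(μ_i, Σ_i),

where f(y_i) is the closed-form LMM marginal (computed through 2×2
Woodbury identities on per-subject sufficient statistics) and the
posterior moments are analytic.  The remaining expectation is evaluated
with Gauss–Hermite quadrature *centered and scaled at the posterior*.
This matters: with the realistic defaults used here the random-intercept
prior SD (12 % predicted) is roughly ten times the per-subject posterior
SD after seven visits, and a prior-scaled rule at practical node counts
places almost no nodes where the integrand lives.  Posterior-centering
keeps 9 nodes per dimension accurate to ~1e-5 in the total
log-likelihood (verified against dense-grid integration in the tests).
For the slope association the survival factor involves only u₁, so the
rule is one-dimensional; the current-value association uses the full
two-dimensional tensor rule.  The rule is deterministic, and at α = 0
the likelihood factorises exactly into the LMM marginal plus the
piecewise-exponential survival log-likelihood.

Subjects with no retained measurement contribute survival information
only; their "posterior" is the prior.

## Estimation

Parameters are estimated by maximum likelihood on an unconstrained
scale: log-Cholesky factor of D, log σ, log piece heights, with β and α
free.  Initialisation is two-stage — a standalone ML fit of the LMM
(fixed effects profiled out by GLS, quasi-Newton on the four variance
parameters) and the closed-form events/exposure piecewise-exponential
fit, with α = 0 — followed by L-BFGS-B on the joint likelihood
(ftol 1e-11, bounded log heights in [−12, 8] so empty hazard cells
cannot diverge).  Standard errors come from the central-difference
Hessian at the optimum; parameters pinned at a bound (e.g. a
stratum-interval cell with no events) are excluded from the inversion
and reported with NaN SEs.  Wald CIs on natural scales use the
delta-method mapping, which for HR(k) = exp(−kα) is exact.

Numerical notes, measured on the shipped test suite:

* Reordering subjects permutes floating-point summation; the optimiser
  then stops within ~1e-3 of the same optimum (well below any
  statistical uncertainty).  The likelihood *value* at fixed parameters
  is order-invariant to ~1e-10.
* The sufficient-statistic formulation cancels catastrophically when
  σ ≲ 0.01 % predicted (residual sums of squares are differences of
  large cross-products), so near-interpolation checks use σ = 0.1.
* A minimum-events guard (default 20) refuses to fit endpoints with too
  few events for a stable 12-piece stratified hazard.
* A day-0 event is shifted to half a day to keep event times positive.

## Endpoint derivation and measurement filtering

The composite event time is the minimum of the first qualifying
hospitalisation day and the day of death; events qualify only inside the
follow-up window (treatment period plus 28 days, `followup_end_days`
taken as input), and the 52-week analysis additionally caps observation
at 52×7 + 28 = 392 days.  Otherwise the subject is censored at the cap.
An `all_cause` endpoint matches any hospitalisation row; the other
categories match their exact tag.  Retained longitudinal responses are
on-treatment, non-missing, strictly before the event/censoring time and
after week 0.  Days convert to years via 365.25.

## Simulator

The generator is the probabilistic inverse of the model above, with
defaults chosen to emulate the published SENSCIS regime: 1:1 allocation,
60.8% ATA-positive, baseline FVC ~ N(72.5, 16.7²) truncated at the 40%
eligibility floor, control slope −2.6 %/yr with a +1.2 %/yr treatment
difference, random-effect SDs 12 (intercept) and 3 (slope) with
correlation −0.2, residual SD 3 — all in % predicted and years — and a
constant baseline hazard of 0.09/0.11 events/year (ATA−/ATA+), which
yields a ~14% 52-week composite event fraction at the default per-unit
hazard ratio of 1.13 (α = −ln 1.13).  Visits follow the trial schedule
(weeks 0–52, extended to week 100 for whole-trial runs).  Event times
are drawn by inverse-CDF sampling, closed-form per hazard piece for both
association structures; the identity Λ_i(T_i) = −ln u_i is tested to
1e-10.  A single seeded stream with fixed draw order (covariates, random
effects, visit noise, event uniforms, event categories, dropout) makes
outputs byte-reproducible and keeps earlier draws unchanged when dropout
is enabled.

What the generator does **not** emulate: visit-level missingness beyond
the event/censoring filter, informative dropout (dropout is independent
of the trajectory), measurement-error autocorrelation, non-linear
trajectories, competing risks between death and hospitalisation, and
any PRO/HRQoL outcomes.  Recovery tests passing on this generator
therefore demonstrate internal statistical correctness of the estimator
under the model's own assumptions, not robustness to the ways real
trial data violate them.

## Scaled experiment sizes

The shipped recovery experiments use 30 replicates of 300-subject
trials (about 42 events each) for effect-size recovery, and 400
replicates of 150-subject whole-trial designs with a raised constant
hazard (0.30/yr, ~75 events, 2 internal knots, 5 quadrature nodes) for
CI-calibration, where each replicate is individually well identified.
At ~42 events the per-replicate SE of α is ~0.13–0.14, so averages of
per-unit hazard ratios over 30 replicates carry a Monte-Carlo SE of
about 0.03 — worth remembering when reading the recovery summaries.

## Known limitations

* Non-adaptive node counts: for extremely long series (hundreds of
  measurements per subject) the posterior becomes so narrow that even
  posterior-centred quadrature could be reduced to Laplace; not needed
  at trial scale.
* The baseline hazard beyond the last knot extrapolates the final piece.
* Left truncation, recurrent events and competing risks are out of
  scope; death and hospitalisation are a single composite.
* The current-value association shares the slope model's knot placement.
* Wald inference on variance parameters uses the transformed scale;
  profile-likelihood intervals are not implemented.
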