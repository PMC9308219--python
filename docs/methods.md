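# Methods

## The model

`varisurv` studies a question that two-stage analyses in clinical research
answer badly: *does the within-subject variability of a longitudinal
biomarker carry prognostic information about a time-to-event outcome, over
and above the biomarker's level and trend?*

The generating (and full Bayesian) model is a shared-parameter joint model
whose longitudinal half is a **mixed-effects location-scale model**: not
only the mean but also the residual (level-1) variance carries a
subject-level random effect.

Measurement sub-model, for subject i at visit time t_ij:

    Y_ij = beta0 + beta1 t_ij + beta2' X_i + I_i + S_i t_ij + e_ij
    e_ij ~ N(0, sigma_vi^2),   log(sigma_vi^2) = mu_v + U_i
    (I_i, S_i, U_i) ~ MVN(0, Sigma)

Sigma has SDs (sigma_I, sigma_S, sigma_V) and free correlations
(rho_12, rho_13, rho_23). U_i is the subject's log-variance deviation: the
latent, error-free measure of within-subject variability.

Intensity sub-model (piecewise-exponential baseline with heights lambda_k
on intervals (t_k, t_{k+1}]):

    lambda_i(t) = lambda0(t) exp(alpha0 + alpha1' Z_i
                                 + gamma1 I_i + gamma2 S_i + gamma3 U_i)

`gamma3` is the target of every estimator in the package: the log hazard
ratio per unit of latent log residual variance.

## Estimators

All two-stage methods share stage-1 summaries: per-subject OLS of the
biomarker on time, giving a fitted intercept, slope, and log residual
variance (at least 3 measurements needed).

* **naive** — one OLS per subject on *all* available visits (so the window
  length is outcome-dependent), then a Cox model treating the summaries as
  exact. `cutoff=0` restricts to pre-baseline data (the
  "no-future-information" variant, equivalent to a single landmark at 0).
* **LMA** — summaries accumulated to each landmark in {0,...,5}; subjects
  still at risk at landmark l enter a stratum with delayed entry at l; one
  stratified Cox over the stacked data with a subject-clustered sandwich
  variance gives the average effect across landmarks. Delayed entry within
  each stratum produces exactly the same risk sets as an unspecified
  per-landmark baseline hazard, which is why the engine expresses
  landmarking through (start, stop] rows rather than per-stratum time
  shifts.
* **td-Cox** — the same accumulating summaries, carried forward as
  time-varying covariates over (u_l, u_{l+1}] in a counting-process Cox.
* **RC** (regression calibration) — stage 1 is the Bayesian location-scale
  mixed model; its per-subject posterior means replace the sample
  summaries. Borrowing strength removes the minimum-measurement rule and
  most of the attenuation.
* **joint** — the full Bayesian fit of both sub-models; no plug-in step.

### A reconstruction note: the residual-variance divisor

The stage-1 "variance of residuals" is computed as the *sample variance of
the OLS residuals* (divisor m−1, as variance functions in standard
statistical software compute it), not the unbiased error-variance estimate
RSS/(m−2). The choice matters only for the naive method: the difference
log((m−1)/(m−2)) depends on the number of measurements m, which for the
naive method is outcome-dependent, while within any LMA stratum or td-Cox
risk set m is common to all subjects and the shift cancels in the partial
likelihood. The m−1 convention reproduces the reference bias values for
the naive estimator; m−2 does not.

### Degenerate stage-1 fits

A subject whose points are exactly collinear (RSS = 0) gets a floored
log variance (log 1e-10) and a `degenerate` flag rather than exclusion —
dropping would couple inclusion to the outcome. Summaries that are
constant across the whole cohort carry no information and are reported as
coefficient 0 with a flag instead of crashing the Cox fit.

## The Cox engine

Newton–Raphson on the stratified partial likelihood over counting-process
risk sets {start < t ≤ stop}, Efron (default) or Breslow ties,
step-halving on likelihood decrease, convergence at relative loglik change
< 1e-9 or gradient max-norm < 1e-6 (max 50 iterations). Risk-set sums are
suffix cumulative sums over stop- and start-sorted rows, so a fit is
O(n log n + E p^2) per iteration. The cluster-robust variance is the
sandwich A⁻¹BA⁻¹ with B built from cluster-summed score residuals; with
tied events each of the d tied subjects receives event share 1/d at each
of d Efron sub-steps, which makes the residuals sum exactly to the score.
Coefficients and SEs agree with lifelines to ~1e-8 on reference data; a
coefficient that diverges past |beta| > 20 flags monotone likelihood.

## The Gibbs sampler

Both Bayesian fits share one Metropolis-within-Gibbs core. The
longitudinal likelihood depends on the data only through per-subject
sufficient statistics (n, Σt, Σt², Σy, Σty, Σy²), so every update is an
O(N) vectorized operation and a full scan costs well under a millisecond
for 500 subjects:

* fixed effects — exact conjugate MVN draw given effects and per-subject
  precisions;
* (I_i, S_i) — exact conjugate bivariate normal given U_i. In the joint
  fit this same conditional serves as an *independence proposal*, accepted
  on the survival-likelihood ratio: it inherits the longitudinal
  information exactly and mixes far better than the random-walk block
  update originally sketched for these triples;
* U_i and mu_v — adaptive scalar random-walk Metropolis (the log variance
  enters non-conjugately), plus a *translation move* (mu_v + d, U_i − d
  for all i) that leaves the likelihood invariant and breaks the strong
  posterior correlation between mu_v and the U field;
* Sigma — conjugate inverse-Wishart;
* hazard heights lambda_k — conjugate gamma updates from the
  interval-exposure (Poisson) augmentation, which matches the exact
  piecewise-exponential likelihood term for term (verified to 1e-10);
* (alpha, gamma) — random-walk Metropolis with Haario-style adaptive
  covariance; because the survival likelihood is cheap, eight sub-steps
  run per scan to keep the weakly identified gamma block mixing.

Priors follow the reference protocol: N(0, 100) on all regression
coefficients and mu_v, Gamma(0.1, rate 1) on hazard heights, and
inverse-Wishart with scale 0.01·I on Sigma. The IW degrees of freedom are
not pinned down by that protocol; the default is 4 (dimension + 1, weakly
informative) and configurable. The hazard intercept alpha0 is fixed at 0
in fitting and absorbed into the lambda_k — the model is not identified
with both — while the simulator keeps alpha0 explicit.

Proposal scales adapt during burn-in (Robbins–Monro toward acceptance
0.44 for scalar moves, 0.234 for the vector block) and freeze afterwards;
a long adaptation period is the default because the level-1 variance
effects adapt slowly. Chains start from crude OLS-based values,
overdispersed across chains. Convergence is monitored by the split-chain
potential scale reduction factor (clamped at 1 from below); any parameter
above 1.1 flags the fit — flagged, never silently accepted.

Validation: on a reference dataset the sampler's posterior agrees with an
independent rjags fit of the identical model/priors within a fraction of
a posterior SD for every parameter (the shortened version of this
comparison runs in the test suite). One honest caveat, documented rather
than hidden: at N = 200 subjects with 10 visits, the frequentist coverage
of the 95% intervals pools to about 86% rather than 95% — the
inverse-Wishart scale 0.01·I is mildly informative for variance
components at that size. The recovery test asserts the calibration the
model actually delivers.

## Simulation design

The generator emulates an eye-pressure-style cohort: biomarker around
24–25 units, a standard-normal baseline covariate entering both sub-models
(beta2 = 1.0 on the biomarker, alpha1 = 0.5 on the hazard), visits on a
fixed semi-annual or quarterly grid with a 1–3 year lead-in before
survival time 0, longitudinal collection ending at year 5, uniform
censoring on [1, 8] years, and event times from an exponential hazard
calibrated (by common-random-number root finding on a pilot cohort) so
that ~80% of subjects are censored. Reference constants: beta0 = 25,
gamma1 = 0.2, gamma2 = 1.0, sigma_I = 2.5, sigma_S = 0.4, mu_v = 1.5,
sigma_V = 0.7, rho = (0.1, 0.2, 0.2). Visits at exactly the event time
are included (closed boundary, configurable); lead-in visits are always
retained.

Experiment 1 crosses visit frequency (semi-annual/quarterly), lead-in
(1/3 years), drift (beta1 = 0/−0.5) and effect (gamma3 = 0/0.5) into 16
scenarios, 500 subjects per cohort. Experiment 2 fixes gamma3 = 0.5
(semi-annual, 2-year lead-in, beta1 = −0.2, alpha0 = 0.5, rho = 0) and
sweeps one variance component at a time.

What the generator does *not* emulate: informative censoring, missed
visits/dropout, measurement-time jitter, or covariate-dependent level-1
variance. Passing tests therefore show estimator behaviour under a
correctly specified model with a regular visit grid — the cleanest setting
for isolating attenuation — not robustness to those real-data features.

### Problem sizes

Replicated experiments use 100 replicates of N = 500 for the sample-based
estimators. The Bayesian methods default to the reference protocol
(3 chains, 15k burn-in + 15k kept) but ship a documented fast profile
(2 chains, 600–800 + 600–800) used by the test suite and the acceptance
script with 15–25 replicates; runs under 30k total iterations are flagged
`scaled_down` in all outputs. Replicate r of scenario s uses seed
base + 10000·s + r, so any replicate reproduces in isolation.

## Known limitations

* The sub-nominal interval coverage at small N noted above.
* Near the boundary sigma_V → 0 the sampler mixes slowly (R-hat ~1.3 at
  4k iterations); estimates remain usable but flagged.
* The landmark estimator reports the stacked average effect; per-landmark
  estimates are exposed (`per_landmark=True`) but not summarized further.
* With the reference correlations (rho_13 = rho_23 = 0.2) and a strong
  slope effect, the attenuated intercept/slope summaries leak a small
  positive bias (~+0.02) into the LMA/td-Cox variability effect at
  gamma3 = 0; zeroing those correlations removes it. This is a property of
  sample-based two-stage estimation, not of the implementation.
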