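# Methods

## Model

Trial-level response times are ex-Gaussian: `RT = N(mu, sigma^2) +
Exp(tau)`, the sum of a Gaussian non-decision component and an
exponentially distributed decision component. Only the exponential mean
carries condition and time effects; the Gaussian SD is constant within a
fit and the Gaussian mean may carry a word-vs-face stimulus-class effect.
Because mean and variance of the exponential component move together,
condition effects on tau reproduce the ubiquitous proportionality of RT
mean and RT spread.

Within each run of dual-stimulus trials the exponential mean follows a
three-parameter saturating trajectory,

    tau(t) = asym + (start - asym) * 2^(-(t - 1) / rate),   t = 1, 2, ...

so `tau(1) = start` exactly and at `t = 1 + rate` half of the
start-to-asymptote change is complete: `rate` is a half-change time
constant in trials. Base 2 with the `(t - 1)` offset is the only form in
which the rate parameter literally equals that definition while the first
trial equals the start level; a base-e trajectory with a rescaled constant
is an equivalent reparameterization, and no claim is made about which
variant other software uses internally.

Each of `log start`, `log rate`, `log asym` and `log mu` (exponential
inverse link, so all four stay positive) is a linear function of
covariates. Categorical covariates use fixed ±0.5 codings (zero-centered
on balanced data): compatibility (incompatible = +0.5), pairing order
(incompatible-first = +0.5), IAT type (alphabetically first level =
+0.5), word-vs-face (word = +0.5). Learning-condition contrasts are
treatment indicators against a reference level; gender and age are
centered at their sample means. Random effects are per-grouping-level
deviations of selected terms (participant intercepts and compatibility
slopes; experiment-level terms for multi-experiment designs), each
component with its own variance.

A useful identity under these codings: a run-level carry-over — a shift
`g` applied to the second run's log asymptote — decomposes exactly as
`g/2 - 2g * (compatibility x order)`, i.e. an intercept shift plus a
compatibility-by-order interaction. The default model spec therefore
includes that interaction, and the generator's ground truth records the
model-scale equivalents.

## Estimation (map backend)

The default backend maximizes a penalized likelihood with analytic
gradients (L-BFGS), in three stages:

1. **Joint stage** — all fixed effects, `log sigma`, and random
   deviations are optimized jointly; random-effect variances are then
   re-estimated by an EM step using conditional variances from a
   finite-difference Hessian, and the solve repeats.
2. **Marginal correction** — joint (plug-in) optimization of nonlinear
   mixed models biases fixed effects, most visibly the rate parameters
   (pilot simulations: about -0.15 to -0.25 on the log scale). The
   package therefore applies a one-step Newton correction on the
   Laplace-approximate marginal objective: the random effects are
   profiled out by an exact per-participant Newton solver (the
   random-effect Hessian is block-diagonal by participant, computed with
   two gradient evaluations per variance component), and the marginal
   objective `-(joint log posterior at the profile mode) + 1/2 log det
   H_bb` is differenced numerically over the ~15 fixed parameters. One
   Newton step from the joint mode is asymptotically equivalent to the
   full marginal optimum and restores near-nominal interval coverage
   (~0.98 across pilot replicates, versus ~0.93 for the plug-in mode).
   Wald intervals come from the marginal Hessian. The step is guarded: if
   the marginal curvature is not positive definite or the step exceeds
   4 SE, the fit falls back to the joint estimates (reported in
   `diagnostics["estimator"]`).
3. The correction currently supports a single grouping factor;
   multi-factor fits (participant + experiment) use the joint estimator.

Priors/penalties: effect coefficients get N(0, 1.5^2) shrinkage;
intercepts are essentially free (SD 5) around plausible anchors (log ms
around 5-6, log trials around 2.5), and `log sigma` around log 50 ms. The
**rate intercept** is the one deliberate exception, N(2.5, 1.5^2):
the likelihood has a degenerate mode at sub-trial time constants in which
the start level turns into a first-trial dummy that chases noise; a time
constant far below one trial is meaningless for a trajectory defined on
trials, and the prior suppresses that mode while leaving any
interpretable rate (fractions of a trial to hundreds of trials)
essentially unpenalized.

Initialization is moment-based: the Gaussian mean from mean RT minus a
skewness-scale tau guess, and the start/asymptote intercepts from early-
versus late-trial mean RTs, which places the optimizer in the
decaying-tau basin. With weakly identified rates (small samples, few
trials), a slow-rate mode with a poorly constrained asymptote can still
genuinely dominate the objective on unlucky datasets; this is a property
of the model at small n, visible as wide rate/asymptote intervals.

The map path contains no randomness: the same data and spec reproduce the
fit bit-for-bit.

## MCMC backend

`method="mcmc"` runs an affine-invariant ensemble sampler initialized at
the map solution (walker count 2 x dimension + 2 by default), with
variance components fixed at the map-EM estimates. It is intended for
small models (tens of parameters); convergence is reported via split-Rhat
and effective sample size, with warnings above Rhat 1.01 and a
non-convergence flag above 1.05. Posterior percentile intervals replace
the Wald intervals, and a draws-by-trials pointwise log-likelihood matrix
supports PSIS-LOO.

## Model comparison

`compare_loo` compares a time-varying fit against the static null (no
change over time; the constant tau inherits the union of the start and
asymptote covariates). Sampled fits use PSIS-LOO on their pointwise
log-likelihood matrices; map fits use 10-fold cross-validated deviance
with folds stratified by participant, the folds shared between the two
models and each fold refit warm-started with variance components fixed.
`DLOOIC = -2 (elpd_a - elpd_b)`; its SE comes from the pointwise
difference dispersion. A difference is *reliable* when `|DLOOIC| > 4` and
at least 2 SE (the multiplier is configurable; the heuristic's source
phrase — "several standard errors" — fixes no number).

One structural fact matters when reading comparisons of nested models:
on data generated by the simpler model the cross-validated deviance
difference does not center at zero but at roughly +2 x (extra effective
parameters) — CV optimism. With the default comparison pair (about four
extra fixed parameters) that is ~ +8, which the 2-SE rule occasionally
flags — correctly favoring the *null*. `LooResult.favors` distinguishes
"a reliable difference favoring the richer model" from "a reliable
difference favoring the simpler one"; specificity claims should be read
as "the time-varying model is never reliably favored on static data".
For the same reason the recommended comparison spec keeps the random
structure lean (participant deviations on the asymptote and Gaussian-mean
blocks, shared by both arms): every weakly identified extra random
effect adds CV penalty that has nothing to do with the scientific
question of time variation.

## Participant-level indices

`extract_indices` evaluates each participant's fitted trajectory at
compatibility ±0.5 with every other covariate at its centered zero:
starting RT difference (tau at t = 1, incompatible minus compatible, ms),
asymptotic RT difference (ms), and the rate time constant (trials).
These are empirical-Bayes point estimates and are shrunken toward the
population mean; their rank agreement with simulated truth depends on how
much person-level variance the generating process puts in each component
(high for heterogeneous asymptote differences, lower for rates).
`early_late_effect` reports the paired-design Cohen's d of the fitted
trial-type difference at the last versus first trial (negative d = the
IAT effect shrank within the session).

## Scoring and filters

The improved D-score computes, per block pair (the 20-trial "practice"
pair, the 40-trial "test" pair), the incompatible-minus-compatible mean
RT difference divided by the SD of all included trials of the pair, then
averages the two subscores — which weights each early trial twice as
heavily as each late one (`effective_trial_weights(20, 40) = 2`).
Incorrect trials are excluded before scoring (no error-penalty variant).
Trial filters: RT window (default 320-2000 ms), incorrect responses;
participant filters: minimum accuracy 80%, at most 10 responses outside
the window; a block-level dialect (accuracy < 70% or block mean RT >
1.5 s) ships as a named preset for aggregated datasets. The empirical
lower cutoff scans 10-ms RT bins upward, pooled across participants, and
returns the lower edge of the first bin whose accuracy beats chance by a
one-sided binomial test (default alpha 0.05; note the scan is a
multiple-testing procedure, so strict alphas are appropriate when many
empty-of-signal bins precede the step). Pooling across participants is an
assumption; a per-participant variant is not implemented.

## Robust linkage regressions

Multivariate outliers among the participant-level variables are rejected
by robust Mahalanobis distances from a raw minimum-covariance-determinant
estimator: a deterministic, seeded multi-start C-step search over
h-subsets (h = 80% of cases by default; all elemental starts are
enumerated when few enough), with the chi-square consistency correction
and flagging at the chi-square(p) 0.99 quantile (alpha 0.01).
`h_fraction = 1` reduces to classical Mahalanobis distances. Indices and
outcomes are z-scored, then each outcome is regressed on each IAT index
with the interaction structure index x motivation scale x interviewer
race (IMS for the seeming-racist rating, EMS for seating distance, plus a
Black-experimenter-only subset model), by Huber M-estimation (tuning
1.345, 95% Gaussian efficiency) bootstrapped over participants (5,000
resamples by default; percentile 95% CIs; a term is reliable when 0 lies
outside its CI). Bootstrap CIs are percentile, not bias-corrected.

## Synthetic data

The generator emulates the standardized 7-block IAT: per IAT type, two
counterbalanced runs of 60 dual-stimulus trials (a 20-trial block feeding
trials 1-20 and a 40-trial block feeding 21-60); single-stimulus training
blocks are not emitted (no analysis consumes them). Population defaults
are at the scale of real online race-IAT fits: log Gaussian mean 6.161,
log start 5.878, log asym 5.112, log rate 2.451; Gaussian SD 50 ms
(within the range typical of RT data; not separately printed by the
sources the scale defaults come from); compatibility effects 0.374 /
0.342 / 0.658 on log start/asym/rate; word-vs-face 0.127 on the log
Gaussian mean. Person-level SDs default to 0.25-0.30 for trajectory
intercepts and 0.15 for compatibility slopes — chosen once as realistic
moderate heterogeneity. The carry-over effect is a configurable shift
(default -0.15) on the second run's log asymptote, which induces the
pairing-order effect on D-scores and on asymptotic RTs. Accuracy is
logistic in RT with a chance floor below 300 ms (width 10 ms), present
only so accuracy-based filters and the empirical cutoff can be exercised.
External measures are linear combinations of z-scored latent components
(true indices, IMS/EMS, interviewer race, and products thereof) plus
Gaussian noise, mapped to instrument scales. A `static` flag ties the
start to the asymptote cell-by-cell, generating the no-change null.

What the generator does *not* emulate: stimulus-level content and
item-level variance, response conflict processes, post-error slowing,
fatigue or non-monotone dynamics, and missing data. Passing recovery
tests therefore demonstrates internal consistency of model and estimator
under the stated generating process, not validity for any particular
real dataset.

## Test conditions and problem sizes

The heavier simulation checks use: parameter recovery, 20 replicates of
60 participants x 120 trials (about 310 parameters per fit with the
default spec); model selection, 20 replicates per arm of 40 participants
x 120 trials with the lean comparison spec; index recovery, 25-60
participants with elevated compatibility-slope heterogeneity (0.35-0.45)
so the target component carries identifiable signal. Interval-calibration
is asserted one-sidedly (undercoverage rejected at binomial alpha 0.01;
conservative intervals pass), matching the scientific concern. Smaller
unit fixtures use 4-15 participants.

## Known limitations

* The marginal correction is one Newton step, not a full marginal
  optimization, and supports one grouping factor; variance components are
  EM point estimates (no uncertainty propagated from them).
* Wald/percentile intervals are symmetric-in-construction on the log
  scale; strongly skewed small-sample posteriors (rates at n of a few
  dozen) are better served by the mcmc backend.
* K-fold deviance for map fits is a plug-in approximation to Bayesian
  LOO; its optimism offset for nested comparisons is documented above.
* The ensemble sampler scales poorly past ~100 dimensions; hierarchical
  fits of realistic size should use the map backend.
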