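# iatdyn

Time-evolving ex-Gaussian modelling of Implicit Association Test (IAT)
response times.

## The problem

The IAT measures implicit evaluation as the difference in response times
between "compatible" and "incompatible" key-pairing blocks, conventionally
aggregated into a single D-score. Aggregation assumes stationarity: that
the RT on trial 1 of a block comes from the same distribution as the RT on
trial 60. Within-session learning, habituation and self-regulation violate
that assumption, and two participants with identical aggregate scores can
have opposite dynamics — a large initial bias that fades fast versus a
smaller but persistent one.

`iatdyn` is for cognitive and social psychologists who want to decompose
IAT performance into interpretable temporal components instead of a single
average. It provides:

* an **ex-Gaussian trial-level model** — RT = Normal(μ, σ²) + Exp(τ) — in
  which only the exponential mean τ changes over trials:

      τ(t) = asym + (start − asym) · 2^(−(t−1)/rate)

  `start` is τ on the first trial ("initial bias"), `asym` its limit
  ("persistent bias"), and `rate` is a time constant in trials: the number
  of trials past the first at which 50% of the start→asymptote change is
  complete ("self-regulation speed"). All three carry log-scale linear
  predictors (compatibility, pairing order, IAT type, learning-condition
  contrasts) with participant- and experiment-level random effects;
* **fitting backends**: fast penalized maximum likelihood with a Laplace
  marginal-likelihood correction and Wald intervals (`map`, the default),
  and an ensemble-MCMC sampler for small models (`mcmc`);
* **model comparison** against a static (no-change) null via
  cross-validated deviance (PSIS-LOO for sampled fits, participant-
  stratified 10-fold CV for map fits) with the "|ΔLOOIC| > 4 and several
  standard errors" reliability heuristic;
* **conventional scoring**: the improved D-score (practice/test subscores
  averaged, which weights each early trial twice as heavily as each late
  one), RT/accuracy trial filters, and the empirically determined
  above-chance lower RT cutoff;
* **block-level analyses**: paired and Welch contrasts, between-subjects
  blockwise Cohen's d with bootstrap CIs, the pairing-order effect, the
  Wilcoxon signed-rank test, and Fisher-z power for correlations;
* **linkage regressions**: robust Mahalanobis (MCD) multivariate outlier
  rejection and bootstrapped robust (Huber) regressions relating z-scored
  trajectory indices to external behavioural measures, with interaction
  structures involving internal/external motivation scales and
  interviewer race;
* a **synthetic-data generator** that emulates the standard 7-block IAT
  (two runs of 20+40 dual-stimulus trials), with configurable
  compatibility/order/IAT-type effects, person-level heterogeneity,
  an accuracy model with a chance floor, and external measures generated
  from known links to the latent trajectory parameters — so every
  analysis stage can be tested against ground truth.

## Worked example

```python
from iatdyn import (SyntheticConfig, simulate_iat, ModelSpec, fit,
                    fit_null, compare_loo, extract_indices, score_dataset)

cfg = SyntheticConfig(n_participants=40, seed=11)
trials, truth = simulate_iat(cfg)

spec = ModelSpec.study2_default()         # compatibility x order model
result = fit(trials, spec, seed=0)
print(result.fixed_estimates[["target", "term", "estimate",
                              "ci_low", "ci_high"]].round(3))

null = fit_null(trials, spec, seed=0, control={"estimator": "joint"})
full = fit(trials, spec, seed=0, control={"estimator": "joint"})
loo = compare_loo(full, null, trials, seed=0)
print(f"dLOOIC = {loo.looic_diff:.1f} (SE {loo.se_diff:.1f}), "
      f"reliable = {loo.reliable}")
```

Output (abridged):

```
            target           term  estimate  ci_low  ci_high
0        log_start      intercept     5.793   5.664    5.922
1        log_start  compatibility     0.479   0.277    0.682
4         log_rate      intercept     2.630   2.241    3.019
8         log_asym      intercept     5.014   4.868    5.160
9         log_asym  compatibility     0.366   0.164    0.568
12  log_gauss_mean      intercept     6.163   6.129    6.197
dLOOIC = -187.3 (SE 33.4), reliable = True
```

Reading it: the exponential RT component starts around exp(5.79) ≈ 328 ms
and settles near exp(5.01) ≈ 151 ms; incompatible blocks start with a
log-scale penalty of 0.48 that persists at 0.37 asymptotically; and the
time-varying model beats the static null by ~187 LOOIC units — strong
evidence of within-session change. `extract_indices(result)` then returns
per-participant starting/asymptotic RT differences (ms) and rate time
constants (trials) for individual-differences analyses, and
`score_dataset(trials)` the conventional D-scores.

The same pipeline is scriptable from the shell:

```bash
iatdyn simulate --out trials.csv --seed 7 --externals ext.csv
iatdyn score    --trials trials.csv --out scores.csv
iatdyn fit      --trials trials.csv --out fit.csv --seed 0
iatdyn compare  --trials trials.csv --out compare.json --seed 0
iatdyn indices  --trials trials.csv --out indices.csv --seed 0
iatdyn link     --indices indices.csv --externals ext.csv \
                --out link.csv --seed 2
```

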