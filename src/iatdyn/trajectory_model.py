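"""Hierarchical time-evolving ex-Gaussian regression for IAT trials.

The model: each trial's RT is ex-Gaussian.  The Gaussian component is
trial-constant within a fit (its mean may carry a word-vs-face effect; its
SD carries none).  The exponential mean tau follows a three-parameter
saturating trajectory over the trial index within a run, and each of the
log start, log rate (time constant in trials), log asymptote and log
Gaussian mean is a linear function of covariates (exponential inverse
link), with random deviations by grouping factors such as participant or
experiment.

Two fitting backends:

* ``map`` (default): penalized maximum likelihood with analytic gradients,
  variance components re-estimated by Laplace/EM steps, and Wald intervals
  from the penalized-likelihood Hessian.  Deterministic and desk-scale.
* ``mcmc``: affine-invariant ensemble sampling (emcee) around the map
  solution, suitable for small models; arviz supplies convergence
  diagnostics and PSIS-LOO.

Model comparison between a time-varying fit and its static null uses
leave-one-out cross-validated deviance: PSIS-LOO for sampled fits, K-fold
(K = 10, folds stratified by participant) for map fits.  A difference is
"reliable" when |ΔLOOIC| > 4 and at least 2 (configurable) standard errors.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .blockwise_stats import EffectSizeResult
from .data_io import TrialDataset
from .errors import (ComparisonError, ConvergenceWarning, ParameterError,
                     RequirementError, StructuralError)
from .exgauss import _logpdf, _logpdf_grad

__all__ = ["ModelSpec", "FitResult", "LooResult", "Design", "build_design",
           "model_loglik", "fit", "fit_null", "compare_loo",
           "extract_indices", "early_late_effect"]

TARGETS = ("log_start", "log_rate", "log_asym", "log_gauss_mean")
STATIC_TARGETS = ("log_asym", "log_gauss_mean")
_LOG2 = np.log(2.0)

#: weakly-informative prior centers for intercepts (log ms / log trials)
INTERCEPT_ANCHORS = {"log_start": 5.9, "log_rate": 2.5, "log_asym": 5.1,
                     "log_gauss_mean": 6.2}
INTERCEPT_PRIOR_SD = 5.0
#: the rate intercept gets a moderately informative prior: the likelihood
#: has a degenerate mode at sub-trial time constants (rate -> 0 turns the
#: start level into a first-trial dummy), which is meaningless for a
#: trajectory defined on trials; sd 1.5 leaves any interpretable time
#: constant (a fraction of a trial to hundreds of trials) essentially free
RATE_INTERCEPT_PRIOR_SD = 1.5
EFFECT_PRIOR_SD = 1.5
LOG_SIGMA_ANCHOR = np.log(50.0)
LOG_SIGMA_PRIOR_SD = 3.0


@dataclass
class ModelSpec:
    """Per-parameter design specification.

    ``fixed_terms`` maps each target (log_start, log_rate, log_asym,
    log_gauss_mean; only log_asym and log_gauss_mean for a static null) to
    its covariate terms.  ``random_terms`` maps a grouping column
    (``participant_id``, ``experiment_id``) to a target->terms map; random
    terms must be a subset of the fixed terms of the same target.
    """

    fixed_terms: dict
    random_terms: dict = field(default_factory=dict)
    time_varying: bool = True

    def __post_init__(self) -> None:
        allowed = TARGETS if self.time_varying else STATIC_TARGETS
        for tgt, terms in self.fixed_terms.items():
            if tgt not in allowed:
                raise StructuralError(
                    f"target {tgt!r} not allowed "
                    f"({'time-varying' if self.time_varying else 'static'} "
                    f"model); allowed: {allowed}")
            if "intercept" not in terms:
                raise StructuralError(f"target {tgt!r} lacks an intercept")
        if self.time_varying:
            for tgt in ("log_start", "log_rate", "log_asym",
                        "log_gauss_mean"):
                if tgt not in self.fixed_terms:
                    raise StructuralError(f"missing target {tgt!r}")
        else:
            for tgt in STATIC_TARGETS:
                if tgt not in self.fixed_terms:
                    raise StructuralError(f"missing target {tgt!r}")
        for group, per_target in self.random_terms.items():
            for tgt, terms in per_target.items():
                if tgt not in self.fixed_terms:
                    raise StructuralError(
                        f"random terms for unknown target {tgt!r}")
                missing = set(terms) - set(self.fixed_terms[tgt])
                if missing:
                    raise StructuralError(
                        f"random terms {sorted(missing)} of {tgt!r} "
                        f"({group}) are not fixed terms")

    def to_null(self) -> "ModelSpec":
        """The static comparison model: no change over time, otherwise the
        same parameterization (the constant tau inherits the union of the
        start and asymptote covariates)."""
        if not self.time_varying:
            return self
        asym = list(self.fixed_terms["log_asym"])
        for t in self.fixed_terms.get("log_start", []):
            if t not in asym:
                asym.append(t)
        fixed = {"log_asym": asym,
                 "log_gauss_mean": list(self.fixed_terms["log_gauss_mean"])}
        random: dict = {}
        for group, per_target in self.random_terms.items():
            merged: dict = {}
            terms = list(per_target.get("log_asym", []))
            for t in per_target.get("log_start", []):
                if t not in terms:
                    terms.append(t)
            if terms:
                merged["log_asym"] = terms
            if per_target.get("log_gauss_mean"):
                merged["log_gauss_mean"] = list(per_target["log_gauss_mean"])
            if merged:
                random[group] = merged
        return ModelSpec(fixed, random, time_varying=False)

    # -- convenience constructors -------------------------------------
    @classmethod
    def study2_default(cls, order: bool = True) -> "ModelSpec":
        """Single-IAT model: compatibility, and optionally pairing order
        plus its interaction with compatibility, on all three trajectory
        parameters; word-vs-face on the Gaussian mean; participant random
        intercepts and compatibility slopes.

        The compatibility-by-order interaction is what a run-level
        carry-over (second-run asymptote shift) looks like under centered
        codes, so including it keeps the model well-specified for
        order-dependent data."""
        terms = ["intercept", "compatibility"] + \
            (["order", "compatibility:order"] if order else [])
        return cls(
            fixed_terms={
                "log_start": list(terms), "log_rate": list(terms),
                "log_asym": list(terms),
                "log_gauss_mean": ["intercept", "word_vs_face"]},
            random_terms={"participant_id": {
                "log_start": ["intercept", "compatibility"],
                "log_rate": ["intercept"],
                "log_asym": ["intercept", "compatibility"],
                "log_gauss_mean": ["intercept"]}})

    @classmethod
    def study3_default(cls) -> "ModelSpec":
        """Joint two-IAT model: zero-centered IAT-type predictor in fixed
        and random effects, order removed."""
        terms = ["intercept", "compatibility", "iat_type",
                 "compatibility:iat_type"]
        return cls(
            fixed_terms={
                "log_start": list(terms), "log_rate": list(terms),
                "log_asym": list(terms),
                "log_gauss_mean": ["intercept", "word_vs_face"]},
            random_terms={"participant_id": {
                "log_start": ["intercept", "compatibility", "iat_type"],
                "log_rate": ["intercept"],
                "log_asym": ["intercept", "compatibility", "iat_type"],
                "log_gauss_mean": ["intercept"]}})

    @classmethod
    def study4_default(cls, conditions: tuple) -> "ModelSpec":
        """Learning-condition model: condition contrasts (first level =
        reference) crossed with incompatibility, zero-centered gender and
        age covariates, participant intercept + compatibility slope, and
        experiment-level intercept + per-fixed-effect slopes."""
        contrasts = [f"condition[{c}]" for c in conditions[1:]]
        terms = (["intercept"] + contrasts + ["compatibility", "gender",
                                              "age"]
                 + [f"{c}:compatibility" for c in contrasts])
        return cls(
            fixed_terms={
                "log_start": list(terms), "log_rate": list(terms),
                "log_asym": list(terms),
                "log_gauss_mean": ["intercept"]},
            random_terms={
                "participant_id": {
                    "log_start": ["intercept", "compatibility"],
                    "log_asym": ["intercept", "compatibility"]},
                "experiment_id": {
                    "log_start": ["intercept", "compatibility"],
                    "log_asym": ["intercept", "compatibility"]}})

    def to_json(self, path) -> None:
        payload = {"fixed_terms": self.fixed_terms,
                   "random_terms": self.random_terms,
                   "time_varying": self.time_varying}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ModelSpec":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(**payload)


# ---------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------

def _encode_term(term: str, df: pd.DataFrame) -> np.ndarray:
    """Encode one covariate term as a per-trial column.

    Categorical codes are fixed +/-0.5 (zero-centered on balanced data):
    compatibility (incompatible = +0.5), order (incompatible_first = +0.5),
    iat_type (alphabetically first level = +0.5), word_vs_face (word =
    +0.5).  ``condition[Level]`` is a treatment indicator against the
    dataset's reference (any level not named in the spec).  gender and age
    are centered at their participant-level means.  ``a:b`` is the product
    of the encoded components.
    """
    if ":" in term:
        parts = term.split(":")
        return np.prod([_encode_term(p, df) for p in parts], axis=0)
    if term == "intercept":
        return np.ones(len(df))
    if term == "compatibility":
        _need(df, "compatibility", term)
        return np.where(df["compatibility"] == "incompatible", 0.5, -0.5)
    if term == "order":
        _need(df, "condition_order", term)
        return np.where(df["condition_order"] == "incompatible_first",
                        0.5, -0.5)
    if term == "iat_type":
        _need(df, "iat_type", term)
        levels = sorted(df["iat_type"].dropna().unique())
        if len(levels) != 2:
            raise RequirementError(
                f"iat_type term needs exactly 2 levels, found {levels}")
        return np.where(df["iat_type"] == levels[0], 0.5, -0.5)
    if term == "word_vs_face":
        _need(df, "stimulus_class", term)
        return np.where(df["stimulus_class"] == "word", 0.5, -0.5)
    if term.startswith("condition[") and term.endswith("]"):
        _need(df, "condition", term)
        level = term[len("condition["):-1]
        if level not in set(df["condition"].unique()):
            raise RequirementError(f"condition level {level!r} absent")
        return (df["condition"] == level).to_numpy(dtype=float)
    if term in ("gender", "age"):
        _need(df, term, term)
        per = df.groupby("participant_id", observed=True)[term].first()
        centered = df[term].to_numpy(dtype=float) - per.mean()
        return centered
    raise RequirementError(f"unknown model term {term!r}")


def _need(df: pd.DataFrame, column: str, term: str) -> None:
    if column not in df.columns or df[column].isna().all():
        raise RequirementError(
            f"term {term!r} requires dataset column {column!r}")


@dataclass
class _RandomBlock:
    group: str
    target: str
    term: str
    levels: np.ndarray
    group_idx: np.ndarray   # per trial, index into levels
    z: np.ndarray           # per trial encoded term value
    offset: int = 0

    @property
    def size(self) -> int:
        return len(self.levels)

    @property
    def label(self) -> str:
        return f"{self.group}/{self.target}/{self.term}"


@dataclass
class Design:
    """Per-parameter design matrices and the flat parameter layout.

    theta layout: fixed-effect blocks in target order, then the global
    log sigma, then one block of deviations per (group, target, term)
    variance component.
    """

    spec: ModelSpec
    targets: tuple
    X: dict
    columns: dict
    random_blocks: list
    fixed_offsets: dict
    sigma_index: int
    n_params: int
    rt: np.ndarray
    trial_t: np.ndarray

    def split_fixed(self, theta: np.ndarray) -> dict:
        return {t: theta[o:o + len(self.columns[t])]
                for t, o in self.fixed_offsets.items()}


def build_design(spec: ModelSpec, dataset: TrialDataset) -> Design:
    """Construct per-target design matrices and the parameter layout.

    Only dual-stimulus trials (non-null compatibility) enter the model.
    Column ordering is deterministic: the spec's term order per target.
    """
    df = dataset.records
    df = df[df["compatibility"].notna() & df["rt_ms"].notna()]
    df = df.reset_index(drop=True)
    if not len(df):
        raise StructuralError("no dual-stimulus trials to model")
    targets = tuple(t for t in TARGETS if t in spec.fixed_terms)
    X, columns, offsets = {}, {}, {}
    pos = 0
    for tgt in targets:
        terms = spec.fixed_terms[tgt]
        cols = [_encode_term(t, df) for t in terms]
        X[tgt] = np.column_stack(cols)
        columns[tgt] = list(terms)
        offsets[tgt] = pos
        pos += len(terms)
    sigma_index = pos
    pos += 1
    blocks: list[_RandomBlock] = []
    for group, per_target in spec.random_terms.items():
        if group not in df.columns:
            raise RequirementError(
                f"random grouping column {group!r} missing from dataset")
        codes, levels = pd.factorize(df[group], sort=True)
        for tgt in [t for t in targets if t in per_target]:
            for term in per_target[tgt]:
                rb = _RandomBlock(group=group, target=tgt, term=term,
                                  levels=np.asarray(levels),
                                  group_idx=codes,
                                  z=_encode_term(term, df), offset=pos)
                pos += rb.size
                blocks.append(rb)
    return Design(spec=spec, targets=targets, X=X, columns=columns,
                  random_blocks=blocks, fixed_offsets=offsets,
                  sigma_index=sigma_index, n_params=pos,
                  rt=df["rt_ms"].to_numpy(dtype=float),
                  trial_t=df["trial_index"].to_numpy(dtype=float))


# ---------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------

def _linear_predictors(design: Design, theta: np.ndarray) -> dict:
    lps = {}
    for tgt in design.targets:
        o = design.fixed_offsets[tgt]
        beta = theta[o:o + len(design.columns[tgt])]
        lps[tgt] = design.X[tgt] @ beta
    for rb in design.random_blocks:
        b = theta[rb.offset:rb.offset + rb.size]
        lps[rb.target] = lps[rb.target] + b[rb.group_idx] * rb.z
    return lps


def _pointwise_loglik(design: Design, theta: np.ndarray,
                      rows: Optional[np.ndarray] = None) -> np.ndarray:
    lps = _linear_predictors(design, theta)
    sigma = np.exp(theta[design.sigma_index])
    mu = np.exp(lps["log_gauss_mean"])
    if design.spec.time_varying:
        start = np.exp(lps["log_start"])
        rate = np.exp(lps["log_rate"])
        asym = np.exp(lps["log_asym"])
        w = np.exp2(-(design.trial_t - 1.0) / rate)
        tau = asym + (start - asym) * w
    else:
        tau = np.exp(lps["log_asym"])
    ll = _logpdf(design.rt, mu, sigma, tau)
    return ll if rows is None else ll[rows]


def model_loglik(dataset: TrialDataset, spec: ModelSpec,
                 theta: np.ndarray) -> np.ndarray:
    """Per-trial log-likelihood at a full parameter vector.

    ``theta`` follows the :class:`Design` layout (fixed blocks per target,
    global log sigma, then random-effect blocks).
    """
    design = build_design(spec, dataset)
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (design.n_params,):
        raise ParameterError(
            f"theta has length {len(theta)}, design needs {design.n_params}")
    return _pointwise_loglik(design, theta)


def _loglik_and_grad(design: Design, theta: np.ndarray,
                     mask: Optional[np.ndarray] = None
                     ) -> tuple[float, np.ndarray]:
    """Data log-likelihood (optionally over a trial mask) and its gradient."""
    lps = _linear_predictors(design, theta)
    sigma = np.exp(theta[design.sigma_index])
    mu = np.exp(lps["log_gauss_mean"])
    tv = design.spec.time_varying
    if tv:
        start = np.exp(lps["log_start"])
        rate = np.exp(lps["log_rate"])
        asym = np.exp(lps["log_asym"])
        tmo = design.trial_t - 1.0
        w = np.exp2(-tmo / rate)
        tau = asym + (start - asym) * w
    else:
        tau = np.exp(lps["log_asym"])
    ll = _logpdf(design.rt, mu, sigma, tau)
    d_mu, d_sigma, d_tau = _logpdf_grad(design.rt, mu, sigma, tau)
    if mask is not None:
        sel = mask.astype(float)
        ll = ll * sel
        d_mu, d_sigma, d_tau = d_mu * sel, d_sigma * sel, d_tau * sel
    g = {}
    g["log_gauss_mean"] = d_mu * mu
    if tv:
        g["log_start"] = d_tau * start * w
        g["log_asym"] = d_tau * asym * (1.0 - w)
        g["log_rate"] = d_tau * (start - asym) * w * _LOG2 * tmo / rate
    else:
        g["log_asym"] = d_tau * tau
    grad = np.zeros(design.n_params)
    for tgt in design.targets:
        o = design.fixed_offsets[tgt]
        grad[o:o + len(design.columns[tgt])] = design.X[tgt].T @ g[tgt]
    grad[design.sigma_index] = float(np.sum(d_sigma * sigma))
    for rb in design.random_blocks:
        grad[rb.offset:rb.offset + rb.size] = np.bincount(
            rb.group_idx, weights=g[rb.target] * rb.z, minlength=rb.size)
    return float(np.sum(ll)), grad


def _prior_and_grad(design: Design, theta: np.ndarray, sds: np.ndarray
                    ) -> tuple[float, np.ndarray]:
    """Log prior/penalty and gradient; sds holds one SD per random block."""
    lp = 0.0
    grad = np.zeros(design.n_params)
    for tgt in design.targets:
        o = design.fixed_offsets[tgt]
        for j, term in enumerate(design.columns[tgt]):
            m0 = INTERCEPT_ANCHORS[tgt] if term == "intercept" else 0.0
            if term != "intercept":
                s0 = EFFECT_PRIOR_SD
            elif tgt == "log_rate":
                s0 = RATE_INTERCEPT_PRIOR_SD
            else:
                s0 = INTERCEPT_PRIOR_SD
            d = theta[o + j] - m0
            lp -= 0.5 * d * d / s0 ** 2
            grad[o + j] -= d / s0 ** 2
    d = theta[design.sigma_index] - LOG_SIGMA_ANCHOR
    lp -= 0.5 * d * d / LOG_SIGMA_PRIOR_SD ** 2
    grad[design.sigma_index] -= d / LOG_SIGMA_PRIOR_SD ** 2
    for k, rb in enumerate(design.random_blocks):
        b = theta[rb.offset:rb.offset + rb.size]
        lp -= 0.5 * float(np.sum(b * b)) / sds[k] ** 2
        grad[rb.offset:rb.offset + rb.size] -= b / sds[k] ** 2
    return lp, grad


# ---------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------

@dataclass
class FitResult:
    """A fitted trajectory model.

    ``fixed_estimates`` is tidy (target, term, estimate, se, ci_low,
    ci_high); ``random_estimates`` holds per-group deviations on the
    unconstrained (log) scale; ``pointwise_loglik`` is a vector (map) or a
    draws-by-trials matrix (mcmc).
    """

    fixed_estimates: pd.DataFrame
    random_estimates: pd.DataFrame
    pointwise_loglik: np.ndarray
    diagnostics: dict
    seed: int
    spec: ModelSpec
    method: str
    design: Design = field(repr=False, default=None)
    theta: np.ndarray = field(repr=False, default=None)
    variance_components: dict = field(default_factory=dict)
    laplace_cov: Optional[np.ndarray] = field(repr=False, default=None)
    draws: Optional[np.ndarray] = field(repr=False, default=None)

    def coef(self, target: str, term: str) -> float:
        f = self.fixed_estimates
        row = f[(f["target"] == target) & (f["term"] == term)]
        if not len(row):
            raise KeyError(f"no coefficient {target}/{term}")
        return float(row["estimate"].iloc[0])

    def to_csv(self, path) -> None:
        """Tidy coefficient export: parameter, coefficient, estimate, CI."""
        self.fixed_estimates.to_csv(path, index=False)


@dataclass
class LooResult:
    """Cross-validated deviance comparison of two fits (a minus b).

    ``reliable`` applies the magnitude heuristic (|ΔLOOIC| > 4 and at
    least ``se_multiplier`` standard errors); ``favors`` says which model
    a reliable difference supports ("a" when ΔLOOIC < 0, "b" when > 0,
    None when the difference is not reliable).  Nested comparisons on
    data generated by the simpler model sit at a positive ΔLOOIC of about
    twice the extra parameter count (cross-validation optimism), so a
    reliable difference favoring the simpler model is the expected
    outcome there, not evidence for the richer one.
    """

    elpd_diff: float
    looic_diff: float
    se_diff: float
    reliable: bool
    method: str
    elpd_a: float = np.nan
    elpd_b: float = np.nan

    @property
    def favors(self) -> Optional[str]:
        if not self.reliable or self.looic_diff == 0:
            return None
        return "a" if self.looic_diff < 0 else "b"


_DEFAULT_CONTROL = {
    "maxiter": 2000, "gtol": 1e-6, "em_iterations": 2,
    "initial_random_sd": 0.3, "min_random_sd": 0.02,
    # "marginal": Laplace-approximate marginal likelihood for the fixed
    # parameters (integrates the random effects out; removes the joint-mode
    # bias of nonlinear plug-in estimation).  "joint": penalized joint
    # optimum only — faster, adequate for prediction-oriented uses such as
    # cross-validated model comparison.
    "estimator": "marginal",
    "outer_maxiter": 200,
    # mcmc
    "n_steps": 1500, "n_burn": 500, "n_walkers": None,
    "n_loglik_draws": 400,
}


def _initial_theta(design: Design) -> np.ndarray:
    """Moment-based start values.

    The Gaussian mean is anchored at mean(RT) minus a skewness-scale tau
    guess; the start and asymptote intercepts come from early- vs
    late-trial mean RTs, which places the optimizer in the basin of the
    decaying-tau solution rather than a degenerate slow-rate mode."""
    rt = design.rt
    t = design.trial_t
    m, s = float(np.mean(rt)), float(np.std(rt))
    tau0 = max(30.0, 0.8 * s)
    sigma0 = np.sqrt(max(s ** 2 - tau0 ** 2, 400.0))
    mu0 = max(m - tau0, 150.0)
    early = float(np.mean(rt[t <= 10])) if np.any(t <= 10) else m
    late = float(np.mean(rt[t >= 30])) if np.any(t >= 30) else m
    tau_start = float(np.clip(early - mu0, 40.0, 3000.0))
    tau_asym = float(np.clip(late - mu0, 20.0, 3000.0))
    theta = np.zeros(design.n_params)
    anchors = {"log_start": np.log(tau_start),
               "log_rate": np.log(10.0),
               "log_asym": np.log(tau_asym),
               "log_gauss_mean": np.log(mu0)}
    for tgt in design.targets:
        o = design.fixed_offsets[tgt]
        j = design.columns[tgt].index("intercept")
        theta[o + j] = anchors[tgt]
    theta[design.sigma_index] = np.log(sigma0)
    return theta


def _solve_map(design: Design, theta0: np.ndarray, sds: np.ndarray,
               control: dict, mask: Optional[np.ndarray] = None
               ) -> optimize.OptimizeResult:
    n = len(design.rt) if mask is None else max(int(mask.sum()), 1)

    def objective(theta):
        ll, gll = _loglik_and_grad(design, theta, mask)
        lp, glp = _prior_and_grad(design, theta, sds)
        return -(ll + lp) / n, -(gll + glp) / n

    return optimize.minimize(
        objective, theta0, jac=True, method="L-BFGS-B",
        options={"maxiter": control["maxiter"], "gtol": control["gtol"],
                 "maxcor": 20})


def _fd_hessian(design: Design, theta: np.ndarray, sds: np.ndarray,
                step: float = 1e-5) -> np.ndarray:
    """Hessian of the negative penalized log-likelihood by central
    differences of the analytic gradient."""
    n = design.n_params
    H = np.empty((n, n))
    for j in range(n):
        tp = theta.copy(); tp[j] += step
        tm = theta.copy(); tm[j] -= step
        _, gp_ll = _loglik_and_grad(design, tp)
        _, gp_pr = _prior_and_grad(design, tp, sds)
        _, gm_ll = _loglik_and_grad(design, tm)
        _, gm_pr = _prior_and_grad(design, tm, sds)
        H[j] = -((gp_ll + gp_pr) - (gm_ll + gm_pr)) / (2 * step)
    return 0.5 * (H + H.T)


class _MarginalProblem:
    """Laplace-approximate marginal likelihood over the fixed parameters.

    The random effects are profiled out: for each candidate fixed vector
    ``phi`` (all fixed-effect blocks plus log sigma) the deviations ``b``
    are re-optimized and the marginal log-likelihood is approximated as
    the joint log-posterior at the mode minus half the log-determinant of
    the random-effect Hessian.  Because every trial belongs to exactly one
    grouping level, that Hessian is block-diagonal by level and is
    computed with two gradient evaluations per variance component.

    Requires all random terms to share one grouping column.
    """

    def __init__(self, design: Design, sds: np.ndarray, theta0: np.ndarray):
        groups = {rb.group for rb in design.random_blocks}
        if len(groups) != 1:
            raise StructuralError(
                "marginal estimator supports a single grouping factor")
        self.design = design
        self.sds = sds
        self.phi_dim = design.sigma_index + 1
        self.b = theta0[self.phi_dim:].copy()
        self.b_ref = self.b.copy()   # reset point for FD sweeps
        self.K = len(design.random_blocks)
        self.L = design.random_blocks[0].size

    def _joint(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        ll, g = _loglik_and_grad(self.design, theta)
        lp, gp = _prior_and_grad(self.design, theta, self.sds)
        return ll + lp, g + gp

    def _hbb_at(self, th: np.ndarray) -> np.ndarray:
        """Per-level random-effect Hessian blocks, shape (L, K, K)."""
        h = 1e-5
        H = np.zeros((self.L, self.K, self.K))
        for k, rb in enumerate(self.design.random_blocks):
            tp = th.copy(); tp[rb.offset:rb.offset + rb.size] += h
            tm = th.copy(); tm[rb.offset:rb.offset + rb.size] -= h
            _, gp = self._joint(tp)
            _, gm = self._joint(tm)
            dg = -(gp - gm) / (2.0 * h)
            for m, rbm in enumerate(self.design.random_blocks):
                H[:, m, k] = dg[rbm.offset:rbm.offset + rbm.size]
        return 0.5 * (H + np.transpose(H, (0, 2, 1)))

    def _grid(self, v: np.ndarray) -> np.ndarray:
        """Reshape a random-coordinate vector to (L, K)."""
        G = np.empty((self.L, self.K))
        for m, rb in enumerate(self.design.random_blocks):
            o = rb.offset - self.phi_dim
            G[:, m] = v[o:o + rb.size]
        return G

    def _ungrid(self, G: np.ndarray) -> np.ndarray:
        v = np.empty(self.K * self.L)
        for m, rb in enumerate(self.design.random_blocks):
            o = rb.offset - self.phi_dim
            v[o:o + rb.size] = G[:, m]
        return v

    def solve_b(self, phi: np.ndarray) -> tuple[float, np.ndarray]:
        """Profile the random deviations at fixed ``phi``.

        Damped (Levenberg-regularized) Newton with exact per-level Hessian
        blocks — the levels are independent given ``phi`` — warm-started
        from the previous solution, recomputing the blocks every
        iteration.  Converges to near machine precision, so the marginal
        objective is smooth enough for finite differencing.  Returns the
        joint log-posterior at the mode and the Hessian blocks there.
        """
        th = np.concatenate([phi, self.b])
        val, grad = self._joint(th)
        if not np.isfinite(val):
            return -np.inf, None
        H = None
        lam = 0.0
        eye = np.eye(self.K)
        for _ in range(60):
            gb = grad[self.phi_dim:]
            H = self._hbb_at(th)
            if float(np.max(np.abs(gb))) < 1e-9 * max(1.0, abs(val)):
                break
            G = self._grid(gb)
            for _try in range(8):
                try:
                    step = self._ungrid(
                        np.linalg.solve(H + lam * eye, G[..., None])[..., 0])
                except np.linalg.LinAlgError:
                    lam = max(4.0 * lam, 1e-4)
                    continue
                if np.all(np.isfinite(step)):
                    break
                lam = max(4.0 * lam, 1e-4)
            else:
                break
            improved = False
            t = 1.0
            while t > 1e-8:
                th_new = th.copy()
                th_new[self.phi_dim:] += t * step
                val_new, grad_new = self._joint(th_new)
                if np.isfinite(val_new) and val_new >= val - 1e-12:
                    improved = val_new > val
                    th, val, grad = th_new, val_new, grad_new
                    break
                t /= 2.0
            if not improved:
                lam = max(4.0 * lam, 1e-4)
                if lam > 1e6:
                    break
            else:
                lam /= 10.0
            if float(np.max(np.abs(t * step))) < 1e-11:
                break
        self.b = th[self.phi_dim:]
        return float(val), H

    def set_reference(self, phi: np.ndarray) -> None:
        """Profile at ``phi`` and remember the solution (and its Hessian
        blocks) as the warm-start reference for finite-difference sweeps."""
        self.solve_b(phi)
        self.b_ref = self.b.copy()

    def objective(self, phi: np.ndarray, from_ref: bool = True) -> float:
        """Negative Laplace marginal log-posterior (constants dropped)."""
        if from_ref:
            self.b = self.b_ref.copy()
        for _attempt in range(2):
            ljoint, H = self.solve_b(phi)
            if H is not None and np.isfinite(ljoint):
                sign, logdet = np.linalg.slogdet(H)
                if np.all(sign > 0):
                    return -ljoint + 0.5 * float(np.sum(logdet))
            self.b = self.b_ref.copy()  # cold retry from the reference
        return 1e10

    def gradient(self, phi: np.ndarray, step: float = 1e-4) -> np.ndarray:
        """Central-difference gradient of the marginal objective."""
        g = np.empty(len(phi))
        for i in range(len(phi)):
            e = np.zeros(len(phi)); e[i] = step
            g[i] = (self.objective(phi + e)
                    - self.objective(phi - e)) / (2 * step)
        return g

    def conditional_variances(self, phi: np.ndarray) -> np.ndarray:
        """diag of H_bb^-1 per random coordinate, in theta order."""
        _, H = self.solve_b(phi)
        inv = np.linalg.inv(H)
        out = np.empty(self.K * self.L)
        for m, rb in enumerate(self.design.random_blocks):
            out[rb.offset - self.phi_dim:
                rb.offset - self.phi_dim + rb.size] = inv[:, m, m]
        return out

    def hessian_phi(self, phi: np.ndarray, step: float = 1e-4) -> np.ndarray:
        """Central-difference Hessian of the marginal objective."""
        p = len(phi)
        f0 = self.objective(phi)
        H = np.empty((p, p))
        fp = np.empty(p)
        fm = np.empty(p)
        for i in range(p):
            e = np.zeros(p); e[i] = step
            fp[i] = self.objective(phi + e)
            fm[i] = self.objective(phi - e)
            H[i, i] = (fp[i] - 2 * f0 + fm[i]) / step ** 2
        for i in range(p):
            for j in range(i + 1, p):
                ei = np.zeros(p); ei[i] = step
                ej = np.zeros(p); ej[j] = step
                H[i, j] = H[j, i] = (
                    self.objective(phi + ei + ej)
                    - self.objective(phi + ei - ej)
                    - self.objective(phi - ei + ej)
                    + self.objective(phi - ei - ej)) / (4 * step ** 2)
        return H


def _fixed_frame(design: Design, theta: np.ndarray,
                 cov: Optional[np.ndarray]) -> pd.DataFrame:
    rows = []
    for tgt in design.targets:
        o = design.fixed_offsets[tgt]
        for j, term in enumerate(design.columns[tgt]):
            est = theta[o + j]
            se = np.sqrt(max(cov[o + j, o + j], 0.0)) if cov is not None \
                else np.nan
            rows.append({"target": tgt, "term": term, "estimate": est,
                         "se": se, "ci_low": est - 1.96 * se,
                         "ci_high": est + 1.96 * se})
    return pd.DataFrame(rows)


def _random_frame(design: Design, theta: np.ndarray) -> pd.DataFrame:
    rows = []
    for rb in design.random_blocks:
        b = theta[rb.offset:rb.offset + rb.size]
        for lev, val in zip(rb.levels, b):
            rows.append({"group": rb.group, "level": lev,
                         "target": rb.target, "term": rb.term,
                         "value": val})
    return pd.DataFrame(rows)


def fit(dataset: TrialDataset, spec: ModelSpec, method: str = "map",
        seed: int = 0, control: Optional[dict] = None) -> FitResult:
    """Fit the hierarchical time-evolving ex-Gaussian model.

    ``map``: penalized-likelihood optimum with Laplace (Wald) intervals;
    variance components of the random effects are re-estimated by
    Laplace/EM steps.  ``mcmc``: emcee ensemble sampling initialized at the
    map solution; intervals are posterior percentiles.  Both expose
    per-trial log-likelihoods for cross-validated model comparison and are
    reproducible given ``seed``.
    """
    ctrl = dict(_DEFAULT_CONTROL)
    if control:
        ctrl.update(control)
    design = build_design(spec, dataset)
    if any(rb.group == "participant_id" for rb in design.random_blocks):
        npart = dataset.records["participant_id"].nunique()
        if npart < 2:
            raise StructuralError(
                "participant random effects need >= 2 participants")

    sds = np.full(len(design.random_blocks), ctrl["initial_random_sd"])
    theta = _initial_theta(design)
    res = _solve_map(design, theta, sds, ctrl)
    theta = res.x
    cov = None
    joint_em = ctrl["em_iterations"] if len(design.random_blocks) else 0
    if ctrl["estimator"] == "marginal":
        joint_em = min(joint_em, 1)  # the marginal stage refines sds itself
    for _ in range(joint_em):
        H = _fd_hessian(design, theta, sds)
        cov = _safe_inv(H)
        var_diag = np.clip(np.diag(cov), 0.0, None)
        new_sds = sds.copy()
        for k, rb in enumerate(design.random_blocks):
            sl = slice(rb.offset, rb.offset + rb.size)
            b = theta[sl]
            new_sds[k] = max(np.sqrt(np.mean(b ** 2 + var_diag[sl])),
                             ctrl["min_random_sd"])
        if np.allclose(new_sds, sds, rtol=1e-3):
            sds = new_sds
            break
        sds = new_sds
        res = _solve_map(design, theta, sds, ctrl)
        theta = res.x
        cov = None
    estimator = ctrl["estimator"]
    n_groups = len({rb.group for rb in design.random_blocks})
    if estimator == "marginal" and n_groups > 1:
        estimator = "joint"  # multi-factor fits fall back to the joint mode
    if estimator == "marginal" and design.random_blocks:
        # One-step Newton correction on the Laplace marginal objective,
        # started from the joint mode: removes the plug-in bias of joint
        # optimization (to first order) at a fraction of the cost of a
        # full marginal optimization; SEs come from the marginal Hessian.
        prob = _MarginalProblem(design, sds, theta)
        phi = theta[:design.sigma_index + 1].copy()
        prob.set_reference(phi)
        grad_f = prob.gradient(phi)
        hess_f = prob.hessian_phi(phi)
        marginal_ok = bool(np.all(np.isfinite(grad_f))
                           and np.all(np.isfinite(hess_f)))
        if marginal_ok:
            try:
                delta = np.linalg.solve(hess_f, grad_f)
            except np.linalg.LinAlgError:
                marginal_ok = False
        if marginal_ok:
            cov_phi = _safe_inv(hess_f)
            if np.any(np.diag(cov_phi) <= 0):
                marginal_ok = False  # non-PD marginal curvature: keep joint
        if marginal_ok:
            se_phi = np.sqrt(np.clip(np.diag(cov_phi), 0.0, None))
            # guard against a wild step (non-quadratic region / noisy FD)
            if np.all(np.abs(delta) <= 4.0 * se_phi + 1e-3):
                f_old = prob.objective(phi)
                f_new = prob.objective(phi - delta)
                if np.isfinite(f_new) and f_new < f_old:
                    phi = phi - delta
                prob.set_reference(phi)
            cond_var = prob.conditional_variances(phi)
            new_sds = sds.copy()
            for k, rb in enumerate(design.random_blocks):
                sl = slice(rb.offset - prob.phi_dim,
                           rb.offset - prob.phi_dim + rb.size)
                b = prob.b[sl]
                new_sds[k] = max(np.sqrt(np.mean(b ** 2 + cond_var[sl])),
                                 ctrl["min_random_sd"])
            sds = new_sds
            prob.sds = sds
            prob.solve_b(phi)
            theta = np.concatenate([phi, prob.b])
            cov = np.zeros((design.n_params, design.n_params))
            cov[:prob.phi_dim, :prob.phi_dim] = cov_phi
            idx = np.arange(prob.phi_dim, design.n_params)
            cov[idx, idx] = np.clip(prob.conditional_variances(phi),
                                    0.0, None)
        else:
            estimator = "joint"
    elif estimator not in ("joint", "marginal"):
        raise ParameterError(f"unknown estimator {estimator!r}")
    if cov is None:
        H = _fd_hessian(design, theta, sds)
        cov = _safe_inv(H)

    converged = bool(res.success)
    diagnostics = {
        "converged": converged, "optimizer_message": str(res.message),
        "n_iter": int(res.nit), "objective": float(res.fun),
        "estimator": estimator if design.random_blocks else "joint",
        "variance_components": {rb.label: float(s)
                                for rb, s in zip(design.random_blocks, sds)},
    }
    if not converged:
        warnings.warn(f"map fit did not converge: {res.message}",
                      ConvergenceWarning)

    result = FitResult(
        fixed_estimates=_fixed_frame(design, theta, cov),
        random_estimates=_random_frame(design, theta),
        pointwise_loglik=_pointwise_loglik(design, theta),
        diagnostics=diagnostics, seed=seed, spec=spec, method="map",
        design=design, theta=theta,
        variance_components=diagnostics["variance_components"],
        laplace_cov=cov)
    if method == "map":
        return result
    if method != "mcmc":
        raise ParameterError(f"unknown method {method!r}")
    return _fit_mcmc(dataset, design, result, sds, seed, ctrl)


def _safe_inv(H: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(H)


def _fit_mcmc(dataset: TrialDataset, design: Design, map_fit: FitResult,
              sds: np.ndarray, seed: int, ctrl: dict) -> FitResult:
    """Ensemble sampling around the map solution (small models only)."""
    import arviz as az
    import emcee

    ndim = design.n_params
    n_walkers = ctrl["n_walkers"] or max(2 * ndim + 2, 32)

    def log_prob(theta):
        ll, _ = _loglik_and_grad(design, theta)
        lp, _ = _prior_and_grad(design, theta, sds)
        out = ll + lp
        return out if np.isfinite(out) else -np.inf

    rng = np.random.default_rng(seed)
    scale = np.sqrt(np.clip(np.diag(map_fit.laplace_cov), 1e-8, None))
    p0 = map_fit.theta + 0.3 * scale * rng.standard_normal((n_walkers, ndim))
    sampler = emcee.EnsembleSampler(
        n_walkers, ndim, log_prob,
        moves=emcee.moves.StretchMove(a=1.3))
    sampler.random_state = np.random.RandomState(seed + 1).get_state()
    sampler.run_mcmc(p0, ctrl["n_steps"], progress=False)
    chain = sampler.get_chain(discard=ctrl["n_burn"])  # (steps, walkers, dim)
    # arviz expects (chains, draws, dim)
    posterior = np.swapaxes(chain, 0, 1)
    idata = az.from_dict(posterior={"theta": posterior})
    rhat = float(np.nanmax(az.rhat(idata)["theta"].values))
    ess = float(np.nanmin(az.ess(idata)["theta"].values))
    flat = chain.reshape(-1, ndim)
    k = min(ctrl["n_loglik_draws"], len(flat))
    pick = np.random.default_rng(seed + 1).choice(len(flat), size=k,
                                                  replace=False)
    sub = flat[pick]
    pointwise = np.stack([_pointwise_loglik(design, t) for t in sub])

    est = flat.mean(axis=0)
    lo = np.percentile(flat, 2.5, axis=0)
    hi = np.percentile(flat, 97.5, axis=0)
    rows = []
    for tgt in design.targets:
        o = design.fixed_offsets[tgt]
        for j, term in enumerate(design.columns[tgt]):
            rows.append({"target": tgt, "term": term,
                         "estimate": est[o + j],
                         "se": float(flat[:, o + j].std(ddof=1)),
                         "ci_low": lo[o + j], "ci_high": hi[o + j]})
    diagnostics = dict(map_fit.diagnostics)
    diagnostics.update({"rhat_max": rhat, "ess_min": ess,
                        "n_walkers": n_walkers, "n_steps": ctrl["n_steps"],
                        "converged": rhat < 1.05})
    if rhat >= 1.05:
        warnings.warn(f"mcmc did not converge: max R-hat {rhat:.3f}",
                      ConvergenceWarning)
    elif rhat >= 1.01:
        warnings.warn(f"mcmc marginal convergence: max R-hat {rhat:.3f}",
                      ConvergenceWarning)
    return FitResult(
        fixed_estimates=pd.DataFrame(rows),
        random_estimates=_random_frame(design, est),
        pointwise_loglik=pointwise, diagnostics=diagnostics, seed=seed,
        spec=design.spec, method="mcmc", design=design, theta=est,
        variance_components=map_fit.variance_components,
        laplace_cov=map_fit.laplace_cov, draws=flat)


def fit_null(dataset: TrialDataset, spec: ModelSpec, method: str = "map",
             seed: int = 0, control: Optional[dict] = None) -> FitResult:
    """Fit the static comparison model (no change over time)."""
    return fit(dataset, spec.to_null(), method=method, seed=seed,
               control=control)


# ---------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------

def _participant_folds(design: Design, dataset: TrialDataset, k: int,
                       seed: int) -> np.ndarray:
    """Fold assignment per modeled trial, stratified by participant."""
    df = dataset.records
    df = df[df["compatibility"].notna() & df["rt_ms"].notna()]
    pid = df["participant_id"].to_numpy()
    folds = np.empty(len(pid), dtype=int)
    rng = np.random.default_rng(seed)
    for p in pd.unique(pid):
        rows = np.flatnonzero(pid == p)
        lab = np.resize(np.arange(k), len(rows))
        rng.shuffle(lab)
        folds[rows] = lab
    return folds


def _kfold_elpd(fitres: FitResult, dataset: TrialDataset, folds: np.ndarray,
                control: Optional[dict]) -> np.ndarray:
    """Held-out pointwise log-likelihoods via K-fold refitting (map)."""
    ctrl = dict(_DEFAULT_CONTROL)
    ctrl.update({"maxiter": 500})
    if control:
        ctrl.update(control)
    design = fitres.design
    sds = np.array([fitres.variance_components[rb.label]
                    for rb in design.random_blocks]) \
        if design.random_blocks else np.empty(0)
    elpd_i = np.empty(len(design.rt))
    for f in np.unique(folds):
        train = folds != f
        res = _solve_map(design, fitres.theta, sds, ctrl, mask=train)
        ll = _pointwise_loglik(design, res.x)
        elpd_i[~train] = ll[~train]
    return elpd_i


def compare_loo(fit_a: FitResult, fit_b: FitResult, dataset: TrialDataset,
                k: int = 10, seed: int = 0,
                se_multiplier: float = 2.0,
                control: Optional[dict] = None) -> LooResult:
    """Cross-validated deviance comparison (fit_a minus fit_b).

    Both fits must model the identical trial set.  mcmc fits use
    Pareto-smoothed importance-sampling LOO on their pointwise
    log-likelihood matrices; map fits use 10-fold cross-validated deviance
    with folds stratified by participant (shared between the two fits).
    ``reliable`` follows the heuristic |ΔLOOIC| > 4 and
    |ΔLOOIC| >= ``se_multiplier`` x SE(ΔLOOIC).
    """
    na = fit_a.pointwise_loglik.shape[-1]
    nb = fit_b.pointwise_loglik.shape[-1]
    if na != nb or not np.array_equal(fit_a.design.rt, fit_b.design.rt):
        raise ComparisonError("fits are not on the identical trial set")
    if fit_a is fit_b:
        return LooResult(elpd_diff=0.0, looic_diff=0.0, se_diff=0.0,
                         reliable=False, method="self")
    if fit_a.method == "mcmc" and fit_b.method == "mcmc":
        elpd_ai = _psis_loo_pointwise(fit_a)
        elpd_bi = _psis_loo_pointwise(fit_b)
        method = "psis_loo"
    else:
        folds = _participant_folds(fit_a.design, dataset, k, seed)
        elpd_ai = _kfold_elpd(fit_a, dataset, folds, control)
        elpd_bi = _kfold_elpd(fit_b, dataset, folds, control)
        method = f"kfold_{k}"
    d = elpd_ai - elpd_bi
    elpd_diff = float(np.sum(d))
    se_elpd = float(np.sqrt(len(d) * np.var(d, ddof=1)))
    looic_diff = -2.0 * elpd_diff
    se_looic = 2.0 * se_elpd
    reliable = (abs(looic_diff) > 4.0
                and abs(looic_diff) >= se_multiplier * se_looic)
    return LooResult(elpd_diff=elpd_diff, looic_diff=looic_diff,
                     se_diff=se_looic, reliable=bool(reliable),
                     method=method, elpd_a=float(np.sum(elpd_ai)),
                     elpd_b=float(np.sum(elpd_bi)))


def _psis_loo_pointwise(fitres: FitResult) -> np.ndarray:
    import arviz as az
    pw = fitres.pointwise_loglik
    idata = az.from_dict(
        log_likelihood={"rt": pw[np.newaxis, :, :]})
    # single merged chain: relative efficiency fixed at 1
    loo = az.loo(idata, pointwise=True, reff=1.0)
    return np.asarray(loo.loo_i)


# ---------------------------------------------------------------------
# participant-level indices
# ---------------------------------------------------------------------

def _participant_blocks(fitres: FitResult) -> dict:
    out: dict = {}
    for rb in fitres.design.random_blocks:
        if rb.group == "participant_id":
            out[(rb.target, rb.term)] = rb
    if not out:
        raise RequirementError(
            "fit has no participant random effects; indices undefined")
    return out


def _participant_lp(fitres: FitResult, target: str, compat_code: float,
                    levels: np.ndarray, blocks: dict) -> np.ndarray:
    """Linear predictor per participant at compatibility = compat_code,
    every other covariate at zero (its centered reference)."""
    design = fitres.design
    o = design.fixed_offsets[target]
    beta = {term: fitres.theta[o + j]
            for j, term in enumerate(design.columns[target])}
    lp = np.full(len(levels), beta.get("intercept", 0.0))
    lp += compat_code * beta.get("compatibility", 0.0)
    for (tgt, term), rb in blocks.items():
        if tgt != target:
            continue
        b = fitres.theta[rb.offset:rb.offset + rb.size]
        aligned = pd.Series(b, index=rb.levels).reindex(levels).to_numpy()
        if term == "intercept":
            lp += aligned
        elif term == "compatibility":
            lp += compat_code * aligned
    return lp


def extract_indices(fitres: FitResult, zscored: bool = False) -> pd.DataFrame:
    """Per-participant trajectory indices on the response scale.

    Returns one row per participant with the starting RT difference
    (incompatible - compatible tau at t = 1, ms), the rate time constant
    (trials), and the asymptotic RT difference (ms), all evaluated at the
    zero (centered) level of every other covariate.  With ``zscored=True``
    each column is standardized.
    """
    blocks = _participant_blocks(fitres)
    if not fitres.spec.time_varying:
        raise RequirementError(
            "indices need a time-varying fit with log_start and log_rate "
            "random terms")
    for tgt in ("log_start", "log_asym"):
        if (tgt, "intercept") not in blocks:
            raise RequirementError(
                f"missing participant random term: {tgt}/intercept")
    levels = blocks[("log_start", "intercept")].levels
    out = pd.DataFrame({"participant_id": levels})
    for tgt, diff_col in (("log_start", "start_diff_ms"),
                          ("log_asym", "asym_diff_ms")):
        hi = np.exp(_participant_lp(fitres, tgt, +0.5, levels, blocks))
        lo = np.exp(_participant_lp(fitres, tgt, -0.5, levels, blocks))
        out[diff_col] = hi - lo
    out["rate_trials"] = np.exp(
        _participant_lp(fitres, "log_rate", 0.0, levels, blocks))
    if zscored:
        from .linkage_regression import zscore
        for col in ("start_diff_ms", "asym_diff_ms", "rate_trials"):
            out[col] = zscore(out[col])
    return out


def early_late_effect(fitres: FitResult) -> EffectSizeResult:
    """Standardized change in the fitted trial-type difference.

    Paired-design Cohen's d of the per-participant fitted incompatible -
    compatible tau difference at the last modeled trial minus the same
    difference at the first trial: negative d means the IAT effect shrank
    over the task.
    """
    if not fitres.spec.time_varying:
        raise StructuralError(
            "early/late effect is undefined for a static fit")
    blocks = _participant_blocks(fitres)
    levels = blocks[next(iter(blocks))].levels
    t_last = float(np.max(fitres.design.trial_t))
    diffs = {}
    for code in (+0.5, -0.5):
        start = np.exp(_participant_lp(fitres, "log_start", code, levels,
                                       blocks))
        asym = np.exp(_participant_lp(fitres, "log_asym", code, levels,
                                      blocks))
        rate = np.exp(_participant_lp(fitres, "log_rate", code, levels,
                                      blocks))
        w = np.exp2(-(t_last - 1.0) / rate)
        diffs[code] = {"early": start, "late": asym + (start - asym) * w}
    early = diffs[0.5]["early"] - diffs[-0.5]["early"]
    late = diffs[0.5]["late"] - diffs[-0.5]["late"]
    change = late - early
    sd = change.std(ddof=1) if len(change) > 1 else 0.0
    if sd <= 1e-10 * max(1.0, float(np.abs(change).max(initial=0.0))):
        return EffectSizeResult(
            statistic=np.nan, effect_d=0.0 if np.allclose(change, 0) else np.nan,
            ci_low=np.nan, ci_high=np.nan, n=(len(change),),
            kind="paired_t", degenerate=True,
            extra={"mean_change_ms": float(change.mean())})
    t, p = stats.ttest_1samp(change, 0.0)
    return EffectSizeResult(
        statistic=float(t), effect_d=float(change.mean() / sd),
        ci_low=np.nan, ci_high=np.nan, n=(len(change),), kind="paired_t",
        p_value=float(p), extra={"mean_change_ms": float(change.mean())})
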