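"""Linking IAT trajectory indices to external behavioural measures.

Implements the robust analysis chain: minimum-covariance-determinant (MCD)
multivariate outlier rejection, z-scoring of indices, bootstrapped robust
(Huber) linear regression with percentile confidence intervals, and the
suite of index-by-motivation interaction models applied to the
seeming-racist rating and seating distance.

The MCD here is the raw estimator: a deterministic multi-start C-step
search over h-subsets (seeded elemental starts, exhaustive when the number
of elemental subsets is small), with the usual chi-square consistency
correction so squared robust distances are comparable to chi-square
quantiles under normality.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .data_io import ExternalMeasuresTable
from .errors import (DegenerateInputError, ParameterError,
                     RequirementError, StructuralError)

__all__ = [
    "OutlierReport", "RobustRegressionResult", "mcd_outliers", "zscore",
    "robust_lm_boot", "linkage_suite", "results_to_frame",
]

HUBER_T = 1.345  # 95% Gaussian efficiency


@dataclass
class OutlierReport:
    """Robust Mahalanobis distances and outlier flags."""

    robust_distance: np.ndarray     # sqrt of squared robust distance
    cutoff: float                   # chi-square quantile for distance^2
    flagged: np.ndarray
    h_fraction: float
    location: np.ndarray
    scatter: np.ndarray


@dataclass
class RobustRegressionResult:
    """Bootstrapped robust-regression coefficients with percentile CIs."""

    terms: list
    coefficients: np.ndarray        # mean over bootstrap resamples
    ci_low: np.ndarray
    ci_high: np.ndarray
    reliable: np.ndarray            # 0 outside the 95% CI
    n_resamples: int
    n_dropped: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "Predictor": self.terms, "Value": self.coefficients,
            "2.5% CI": self.ci_low, "97.5% CI": self.ci_high,
            "reliable": self.reliable})


def _c_steps(X: np.ndarray, subset: np.ndarray, h: int,
             max_iter: int = 100) -> tuple[float, np.ndarray]:
    """Iterate concentration steps from a starting subset; return
    (log-determinant, final h-subset)."""
    idx = subset
    prev_det = np.inf
    for _ in range(max_iter):
        loc = X[idx].mean(axis=0)
        cov = np.cov(X[idx], rowvar=False, ddof=1)
        sign, logdet = np.linalg.slogdet(cov)
        if sign <= 0:
            return np.inf, idx
        d2 = _mahal_sq(X, loc, cov)
        new_idx = np.argsort(d2, kind="stable")[:h]
        if logdet >= prev_det - 1e-12:
            return logdet, idx
        prev_det = logdet
        idx = new_idx
    return prev_det, idx


def _mahal_sq(X: np.ndarray, loc: np.ndarray, cov: np.ndarray) -> np.ndarray:
    diff = X - loc
    sol = np.linalg.solve(cov, diff.T)
    return np.einsum("ij,ji->i", diff, sol)


def _consistency_factor(h: int, n: int, p: int) -> float:
    frac = h / n
    return frac / stats.chi2.cdf(stats.chi2.ppf(frac, p), p + 2)


def mcd_outliers(X, h_fraction: float = 0.8, alpha: float = 0.01,
                 seed: int = 0, n_starts: int = 500) -> OutlierReport:
    """Flag multivariate outliers via robust (MCD) Mahalanobis distances.

    Parameters
    ----------
    X : array_like or DataFrame, shape (n, p)
        Participant-by-variable matrix.
    h_fraction : float
        Fraction of cases the robust covariance may use, in (0.5, 1].
        ``h_fraction = 1`` reduces to classical Mahalanobis distances.
    alpha : float
        Flagging level: squared distances above the chi-square(p)
        ``1 - alpha`` quantile are outliers.
    seed, n_starts : int
        Elemental (p+1)-subset starts; all subsets are enumerated when
        there are at most ``n_starts`` of them, otherwise ``n_starts``
        seeded random starts are drawn.
    """
    if isinstance(X, pd.DataFrame):
        columns = list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        columns = [f"x{j}" for j in range(X.shape[1])]
    n, p = X.shape
    if n <= p + 1:
        raise ParameterError("need more rows than columns + 1")
    if not 0.5 < h_fraction <= 1.0:
        raise ParameterError("h_fraction must be in (0.5, 1]")
    if np.linalg.matrix_rank(np.cov(X, rowvar=False, ddof=1)) < p:
        corr = np.corrcoef(X, rowvar=False)
        pairs = [(columns[i], columns[j]) for i in range(p)
                 for j in range(i + 1, p) if abs(corr[i, j]) > 1 - 1e-10]
        raise StructuralError(f"singular scatter; collinear columns: {pairs}")

    if h_fraction == 1.0:
        loc = X.mean(axis=0)
        cov = np.cov(X, rowvar=False, ddof=1)
    else:
        h = max(int(np.ceil(h_fraction * n)), (n + p + 1) // 2)
        from math import comb
        if comb(n, p + 1) <= n_starts:
            starts = [np.asarray(s) for s in
                      itertools.combinations(range(n), p + 1)]
        else:
            rng = np.random.default_rng(seed)
            starts = [rng.choice(n, size=p + 1, replace=False)
                      for _ in range(n_starts)]
        best = (np.inf, None)
        for s in starts:
            if np.linalg.matrix_rank(X[s] - X[s].mean(axis=0)) < p:
                continue  # degenerate elemental start
            # one C-step from the elemental fit, then full concentration
            loc0 = X[s].mean(axis=0)
            cov0 = np.cov(X[s], rowvar=False, ddof=1)
            d2 = _mahal_sq(X, loc0, cov0)
            subset = np.argsort(d2, kind="stable")[:h]
            logdet, subset = _c_steps(X, subset, h)
            if logdet < best[0]:
                best = (logdet, subset)
        if best[1] is None:
            raise StructuralError("no non-singular starting subset found")
        subset = best[1]
        loc = X[subset].mean(axis=0)
        cov = (np.cov(X[subset], rowvar=False, ddof=1)
               * _consistency_factor(len(subset), n, p))

    d2 = _mahal_sq(X, loc, cov)
    cutoff = float(stats.chi2.ppf(1 - alpha, p))
    return OutlierReport(
        robust_distance=np.sqrt(d2), cutoff=cutoff, flagged=d2 > cutoff,
        h_fraction=h_fraction, location=loc, scatter=cov)


def zscore(values) -> np.ndarray:
    """Standardize to mean 0, SD 1 (sample SD, ddof=1)."""
    v = np.asarray(values, dtype=float)
    sd = v.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("zero SD: z-score undefined")
    return (v - v.mean()) / sd


def robust_lm_boot(response, design: pd.DataFrame, seed: int,
                   n_boot: int = 5000, huber_t: float = HUBER_T
                   ) -> RobustRegressionResult:
    """Bootstrapped robust (Huber M-estimation) linear regression.

    Cases (rows) are resampled with replacement ``n_boot`` times; each
    resample is fit by iteratively reweighted least squares with a Huber
    loss (tuning constant 1.345 for 95% Gaussian efficiency).  Reported
    coefficients are resample means with percentile 95% CIs; a term is
    ``reliable`` when 0 falls outside its CI.  Non-convergent resamples are
    dropped and counted; more than 1% dropped is an error.
    """
    y = np.asarray(response, dtype=float)
    X = design.to_numpy(dtype=float)
    terms = list(design.columns)
    n, k = X.shape
    if n < 3 * k:
        raise ParameterError(
            f"need >= 3 rows per term: n={n}, terms={k}")
    rng = np.random.default_rng(seed)
    draws = np.full((n_boot, k), np.nan)
    norm = sm.robust.norms.HuberT(t=huber_t)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        Xb, yb = X[idx], y[idx]
        if np.linalg.matrix_rank(Xb) < k:
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.RLM(yb, Xb, M=norm).fit(maxiter=100)
            if res.converged if hasattr(res, "converged") else True:
                draws[b] = res.params
        except (np.linalg.LinAlgError, ValueError):
            continue
    ok = ~np.isnan(draws[:, 0])
    n_dropped = int(n_boot - ok.sum())
    if n_dropped > 0.01 * n_boot:
        raise StructuralError(
            f"{n_dropped}/{n_boot} bootstrap resamples failed to converge")
    good = draws[ok]
    lo = np.percentile(good, 2.5, axis=0)
    hi = np.percentile(good, 97.5, axis=0)
    return RobustRegressionResult(
        terms=terms, coefficients=good.mean(axis=0), ci_low=lo, ci_high=hi,
        reliable=(lo > 0) | (hi < 0), n_resamples=int(ok.sum()),
        n_dropped=n_dropped, seed=seed)


def _interaction_design(z_index: np.ndarray, z_mot: np.ndarray,
                        race_code: np.ndarray, index_name: str,
                        mot_name: str, with_race: bool) -> pd.DataFrame:
    cols = {}
    if with_race:
        cols["IntervWhite"] = race_code
    cols[index_name] = z_index
    cols[mot_name] = z_mot
    if with_race:
        cols[f"IntervWhite:{index_name}"] = race_code * z_index
        cols[f"IntervWhite:{mot_name}"] = race_code * z_mot
    cols[f"{index_name}:{mot_name}"] = z_index * z_mot
    if with_race:
        cols[f"IntervWhite:{index_name}:{mot_name}"] = \
            race_code * z_index * z_mot
    df = pd.DataFrame(cols)
    df.insert(0, "Intercept", 1.0)
    return df


def linkage_suite(indices: pd.DataFrame, externals: ExternalMeasuresTable,
                  seed: int, n_boot: int = 5000,
                  index_columns: tuple = ("overall", "start_diff", "rate",
                                          "asym_diff"),
                  max_join_loss: float = 0.1) -> dict:
    """Fit the index-by-motivation robust regression menu.

    For each IAT index (columns of ``indices``; conventionally the overall
    score, starting difference, rate, and asymptotic difference), fits:

    * ``seeming_racist`` ~ interviewer race x index x IMS
    * ``seating_distance_cm`` ~ interviewer race x index x EMS
    * ``seating_distance_cm`` ~ index x EMS on the Black-experimenter subset

    All indices and outcomes are z-scored before fitting so coefficients
    share a scale.  Returns ``{(outcome, index): RobustRegressionResult}``.
    """
    merged = indices.merge(externals.table, on="participant_id", how="inner")
    loss = 1.0 - len(merged) / max(len(indices), 1)
    if loss > max_join_loss:
        raise StructuralError(
            f"participant join lost {loss:.0%} of {len(indices)} index rows "
            f"(kept {len(merged)}); threshold {max_join_loss:.0%}")
    for col in index_columns:
        if col not in merged.columns:
            raise RequirementError(f"indices table lacks column {col!r}")

    race_code = np.where(merged["interviewer_race"] == "white", 0.5, -0.5)
    black = merged["interviewer_race"] == "black"
    if not black.any():
        raise RequirementError(
            "Black-experimenter subset model requested but no rows with "
            "interviewer_race == 'black'")
    z_ims = zscore(merged["ims"])
    z_ems = zscore(merged["ems"])
    z_seem = zscore(merged["seeming_racist"])
    z_seat = zscore(merged["seating_distance_cm"])

    results: dict = {}
    for j, col in enumerate(index_columns):
        z_idx = zscore(merged[col])
        sub_seed = seed + 1000 * j
        design = _interaction_design(z_idx, z_ims, race_code, "IAT", "IMS",
                                     with_race=True)
        results[("seeming_racist", col)] = robust_lm_boot(
            z_seem, design, seed=sub_seed, n_boot=n_boot)
        design = _interaction_design(z_idx, z_ems, race_code, "IAT", "EMS",
                                     with_race=True)
        results[("seating_distance", col)] = robust_lm_boot(
            z_seat, design, seed=sub_seed + 1, n_boot=n_boot)
        design = _interaction_design(
            z_idx[black.to_numpy()], z_ems[black.to_numpy()],
            race_code[black.to_numpy()], "IAT", "EMS", with_race=False)
        results[("seating_distance_black_exp", col)] = robust_lm_boot(
            z_seat[black.to_numpy()], design, seed=sub_seed + 2,
            n_boot=n_boot)
    return results


def results_to_frame(results: dict) -> pd.DataFrame:
    """Tidy export: one row per (outcome, IAT measure, predictor)."""
    frames = []
    for (outcome, measure), res in results.items():
        f = res.to_frame()
        f.insert(0, "IAT_measure", measure)
        f.insert(0, "outcome", outcome)
        frames.append(f)
    return pd.concat(frames, ignore_index=True)
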