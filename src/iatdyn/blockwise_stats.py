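"""Aggregate block-level contrasts, effect sizes, and power.

These are the conventional analyses applied to block-aggregated IAT data:
paired and Welch t contrasts with Cohen's d, between-subjects blockwise d
with a seeded percentile-bootstrap CI, the order effect on D-scores, the
Wilcoxon signed-rank test, and the Fisher-z power approximation for a
product-moment correlation.

Effect-size conventions: paired contrasts use mean(diff)/SD(diff);
between-subject contrasts use the pooled-SD d.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import DUAL_BLOCKS, TrialDataset
from .errors import DegenerateInputError, ParameterError

__all__ = [
    "EffectSizeResult", "paired_contrast", "welch_contrast", "block_means",
    "blockwise_d", "order_effect", "signrank", "power_correlation",
]

DEFAULT_N_BOOT = 5000


@dataclass
class EffectSizeResult:
    """A contrast statistic with its effect size and interval."""

    statistic: float
    effect_d: float
    ci_low: float
    ci_high: float
    n: tuple
    kind: str
    p_value: Optional[float] = None
    degenerate: bool = False
    extra: dict = field(default_factory=dict)


def paired_contrast(x, y) -> EffectSizeResult:
    """Paired t contrast of y vs x with d = mean(y-x)/SD(y-x).

    The CI is the analytic 95% interval for the mean difference.  A
    constant nonzero difference (zero SD) is flagged degenerate rather
    than raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ParameterError("paired contrast requires equal-length inputs")
    if len(x) < 2:
        raise ParameterError("need >= 2 pairs")
    diff = y - x
    sd = diff.std(ddof=1)
    n = len(diff)
    if sd == 0:
        if np.all(diff == 0):  # identical inputs: a genuine zero effect
            return EffectSizeResult(
                statistic=0.0, effect_d=0.0, ci_low=0.0, ci_high=0.0,
                n=(n,), kind="paired_t", p_value=1.0,
                extra={"mean_diff": 0.0})
        return EffectSizeResult(
            statistic=np.nan, effect_d=np.nan, ci_low=float(diff.mean()),
            ci_high=float(diff.mean()), n=(n,), kind="paired_t",
            degenerate=True)
    t, p = stats.ttest_rel(y, x)
    se = sd / np.sqrt(n)
    tcrit = stats.t.ppf(0.975, n - 1)
    return EffectSizeResult(
        statistic=float(t), effect_d=float(diff.mean() / sd),
        ci_low=float(diff.mean() - tcrit * se),
        ci_high=float(diff.mean() + tcrit * se),
        n=(n,), kind="paired_t", p_value=float(p),
        extra={"mean_diff": float(diff.mean())})


def welch_contrast(a, b) -> EffectSizeResult:
    """Welch t contrast (Satterthwaite df) with pooled-SD Cohen's d.

    The CI is for the difference of means at the Welch degrees of freedom.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ParameterError("each group needs >= 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise DegenerateInputError("both groups are constant")
    na, nb = len(a), len(b)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    df = (va / na + vb / nb) ** 2 / (
        (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    pooled = np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
    mean_diff = a.mean() - b.mean()
    se = np.sqrt(va / na + vb / nb)
    tcrit = stats.t.ppf(0.975, df)
    return EffectSizeResult(
        statistic=float(t), effect_d=float(mean_diff / pooled),
        ci_low=float(mean_diff - tcrit * se),
        ci_high=float(mean_diff + tcrit * se),
        n=(na, nb), kind="welch_t", p_value=float(p),
        extra={"df": float(df), "mean_diff": float(mean_diff)})


def block_means(dataset: TrialDataset) -> pd.DataFrame:
    """Per-participant mean RT of each dual-stimulus block.

    Returns a tidy frame (participant_id, block_index, mean_rt_ms,
    compatibility, condition_order) — the aggregated form blockwise
    contrasts operate on.
    """
    dual = dataset.records[dataset.records["block_index"].isin(DUAL_BLOCKS)]
    out = (dual.groupby(["participant_id", "block_index"], observed=True)
           .agg(mean_rt_ms=("rt_ms", "mean"),
                compatibility=("compatibility", "first"),
                condition_order=("condition_order", "first"))
           .reset_index())
    return out


def _boot_d(a: np.ndarray, b: np.ndarray, n_boot: int, rng) -> tuple:
    ds = np.empty(n_boot)
    for i in range(n_boot):
        ra = a[rng.integers(0, len(a), len(a))]
        rb = b[rng.integers(0, len(b), len(b))]
        va, vb = ra.var(ddof=1), rb.var(ddof=1)
        pooled = np.sqrt(((len(ra) - 1) * va + (len(rb) - 1) * vb)
                         / (len(ra) + len(rb) - 2))
        ds[i] = (ra.mean() - rb.mean()) / pooled if pooled > 0 else 0.0
    return float(np.percentile(ds, 2.5)), float(np.percentile(ds, 97.5))


def blockwise_d(means: pd.DataFrame, block: int, seed: int,
                n_boot: int = DEFAULT_N_BOOT) -> EffectSizeResult:
    """Between-subjects Cohen's d of one block's RTs by compatibility.

    Compares the block's mean RTs between participants for whom that block
    was incompatible vs those for whom it was compatible (pooled-SD d),
    with a seeded percentile-bootstrap 95% CI.
    """
    sub = means[means["block_index"] == block]
    inc = sub.loc[sub["compatibility"] == "incompatible",
                  "mean_rt_ms"].to_numpy()
    com = sub.loc[sub["compatibility"] == "compatible",
                  "mean_rt_ms"].to_numpy()
    if len(inc) < 2 or len(com) < 2:
        raise DegenerateInputError(
            f"block {block}: both compatibility groups must be represented")
    va, vb = inc.var(ddof=1), com.var(ddof=1)
    pooled = np.sqrt(((len(inc) - 1) * va + (len(com) - 1) * vb)
                     / (len(inc) + len(com) - 2))
    d = float((inc.mean() - com.mean()) / pooled)
    rng = np.random.default_rng(seed)
    lo, hi = _boot_d(inc, com, n_boot, rng)
    return EffectSizeResult(
        statistic=d, effect_d=d, ci_low=lo, ci_high=hi,
        n=(len(inc), len(com)), kind="cohen_d_between",
        extra={"block": block})


def order_effect(dscores, order, seed: int,
                 n_boot: int = DEFAULT_N_BOOT) -> EffectSizeResult:
    """Welch contrast of D-scores by pairing order, with bootstrap CIs.

    Contrasts compatible-first vs incompatible-first participants' overall
    D-scores; ``extra`` carries seeded percentile-bootstrap 95% CIs of each
    group mean.
    """
    dscores = np.asarray(dscores, dtype=float)
    order = np.asarray(order)
    groups = {}
    for lab in ("compatible_first", "incompatible_first"):
        g = dscores[order == lab]
        if len(g) < 2:
            raise DegenerateInputError(f"order group {lab!r} absent or too small")
        groups[lab] = g
    res = welch_contrast(groups["compatible_first"],
                         groups["incompatible_first"])
    rng = np.random.default_rng(seed)
    cis = {}
    for lab, g in groups.items():
        boots = np.array([g[rng.integers(0, len(g), len(g))].mean()
                          for _ in range(n_boot)])
        cis[lab] = (float(np.percentile(boots, 2.5)),
                    float(np.percentile(boots, 97.5)),
                    float(g.mean()))
    res.kind = "order_effect"
    res.extra["group_mean_ci"] = cis
    return res


def signrank(x, y) -> EffectSizeResult:
    """Wilcoxon signed-rank test of paired x vs y (differences x - y).

    Reports the signed-rank statistic W (sum of ranks of positive
    differences), a normal-approximation Z, the two-sided p (exact for
    n <= 25 without ties, normal approximation otherwise), and the median
    difference.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ParameterError("signrank requires paired inputs")
    diff = x - y
    nz = diff[diff != 0]
    if len(nz) == 0:
        return EffectSizeResult(
            statistic=np.nan, effect_d=np.nan, ci_low=np.nan, ci_high=np.nan,
            n=(len(diff),), kind="wilcoxon_signrank", degenerate=True,
            extra={"median_diff": 0.0})
    if len(nz) < 5:
        raise ParameterError("need >= 5 non-zero differences")
    n = len(nz)
    ranks = stats.rankdata(np.abs(nz))
    w_plus = float(ranks[nz > 0].sum())
    mean_w = n * (n + 1) / 4.0
    # tie-corrected variance of W+
    _, counts = np.unique(np.abs(nz), return_counts=True)
    var_w = (n * (n + 1) * (2 * n + 1) / 24.0
             - np.sum(counts ** 3 - counts) / 48.0)
    z = (w_plus - mean_w) / np.sqrt(var_w)
    method = "exact" if (n <= 25 and len(counts) == n) else "approx"
    p = float(stats.wilcoxon(nz, method=method).pvalue)
    return EffectSizeResult(
        statistic=w_plus, effect_d=float(z), ci_low=np.nan, ci_high=np.nan,
        n=(n,), kind="wilcoxon_signrank", p_value=p,
        extra={"z": float(z), "median_diff": float(np.median(diff)),
               "method": method})


def power_correlation(n: int, rho: float, alpha: float = 0.05) -> float:
    """Fisher-z power for a two-sided test of a product-moment correlation.

    ``power = P(Z > z_{a/2} - atanh(rho) sqrt(n-3)) +
    P(Z < -z_{a/2} - atanh(rho) sqrt(n-3))``; at rho = 0 this equals alpha.
    """
    if n < 4:
        raise ParameterError("n must be >= 4")
    if not abs(rho) < 1:
        raise ParameterError("|rho| must be < 1")
    if not 0 < alpha < 1:
        raise ParameterError("alpha must be in (0, 1)")
    za = stats.norm.ppf(1 - alpha / 2.0)
    shift = np.arctanh(rho) * np.sqrt(n - 3)
    return float(stats.norm.sf(za - shift) + stats.norm.cdf(-za - shift))
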