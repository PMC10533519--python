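"""Conventional aggregate IAT scoring and trial/participant filtering.

The D-score computes, separately for the 20-trial ("practice") pair of
dual-stimulus blocks and the 40-trial ("test") pair, the incompatible
minus compatible mean RT difference divided by the SD of all included
trials of that pair, and averages the two subscores.  Because the two
subscores receive equal weight while the practice pair has half as many
trials, each early trial influences the overall score twice as heavily as
each late trial.

Incorrect trials are excluded before scoring rather than replaced by
penalty latencies; the error-penalty scoring variant is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .data_io import PRACTICE_BLOCKS, TEST_BLOCKS, TrialDataset
from .errors import (DegenerateInputError, ParameterError, RequirementError,
                     StructuralError)

__all__ = [
    "FilterRules", "DScoreResult", "apply_filters", "empirical_lower_cutoff",
    "d_score", "score_dataset", "effective_trial_weights", "STUDY1_PRESET",
]


@dataclass(frozen=True)
class FilterRules:
    """Trial- and participant-level exclusion rules.

    ``lower_rt_ms`` may be a number or the string ``"empirical"``, in which
    case :func:`empirical_lower_cutoff` determines it from accuracy data.
    Trial-level exclusions (RT window, incorrect responses) are applied
    before participant-level rules (minimum accuracy, maximum number of
    responses outside the RT window, per-block rules).
    """

    lower_rt_ms: Union[float, str] = 320.0
    upper_rt_ms: float = 2000.0
    drop_incorrect: bool = True
    participant_min_accuracy: Optional[float] = 0.8
    participant_max_out_of_window: Optional[int] = 10
    block_min_accuracy: Optional[float] = None
    block_max_mean_rt_ms: Optional[float] = None

    def __post_init__(self) -> None:
        if not isinstance(self.lower_rt_ms, str):
            if not self.lower_rt_ms < self.upper_rt_ms:
                raise ParameterError("lower_rt_ms must be < upper_rt_ms")
        elif self.lower_rt_ms != "empirical":
            raise ParameterError(
                f"lower_rt_ms must be a number or 'empirical', got "
                f"{self.lower_rt_ms!r}")
        for name in ("participant_min_accuracy", "block_min_accuracy"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1]")


#: Block-level dialect used for large aggregated datasets: drop a
#: participant whose accuracy falls below 70% or whose mean RT exceeds
#: 1.5 s on at least one block.
STUDY1_PRESET = FilterRules(
    lower_rt_ms=0.0, upper_rt_ms=float("inf"), drop_incorrect=False,
    participant_min_accuracy=None, participant_max_out_of_window=None,
    block_min_accuracy=0.70, block_max_mean_rt_ms=1500.0)


@dataclass
class DScoreResult:
    """Aggregate IAT indices for one participant (and IAT type)."""

    d_practice: float
    d_test: float
    d_overall: float
    mean_diff_ms: float
    n_trials_used: int
    exclusion_report: dict = field(default_factory=dict)


def _trial_mask(df: pd.DataFrame, rules: FilterRules, lower: float) -> dict:
    masks = {
        "rt_below_lower": df["rt_ms"] < lower,
        "rt_above_upper": df["rt_ms"] > rules.upper_rt_ms,
    }
    if rules.drop_incorrect:
        if "correct" not in df.columns or df["correct"].isna().all():
            raise RequirementError(
                "drop_incorrect requires an accuracy ('correct') column")
        masks["incorrect"] = ~df["correct"].astype(bool)
    return masks


def apply_filters(dataset: TrialDataset, rules: FilterRules
                  ) -> tuple[TrialDataset, dict]:
    """Apply exclusion rules; return the filtered dataset and a report.

    The report gives per-rule exclusion counts (a trial excluded by several
    rules counts once per rule), participants removed, and the retained
    fraction of trials.
    """
    df = dataset.records
    if isinstance(rules.lower_rt_ms, str):
        lower = empirical_lower_cutoff(dataset)
    else:
        lower = float(rules.lower_rt_ms)
    needs_acc = (rules.drop_incorrect
                 or rules.participant_min_accuracy is not None
                 or rules.block_min_accuracy is not None)
    if needs_acc and "correct" not in df.columns:
        raise RequirementError("accuracy rules require a 'correct' column")

    masks = _trial_mask(df, rules, lower)
    report = {rule: int(m.sum()) for rule, m in masks.items()}
    report["lower_rt_ms_used"] = lower
    excluded = np.logical_or.reduce([m.to_numpy() for m in masks.values()])

    # participant-level rules are judged on the unfiltered trials
    drop_pids: set = set()
    if rules.participant_min_accuracy is not None:
        acc = df.groupby("participant_id", observed=True)["correct"].mean()
        drop_pids |= set(acc[acc < rules.participant_min_accuracy].index)
    if rules.participant_max_out_of_window is not None:
        oow = ((df["rt_ms"] < lower) | (df["rt_ms"] > rules.upper_rt_ms))
        cnt = oow.groupby(df["participant_id"], observed=True).sum()
        drop_pids |= set(cnt[cnt >= rules.participant_max_out_of_window].index)
    if rules.block_min_accuracy is not None:
        bacc = df.groupby(["participant_id", "block_index"],
                          observed=True)["correct"].mean()
        drop_pids |= set(bacc[bacc < rules.block_min_accuracy]
                         .index.get_level_values(0))
    if rules.block_max_mean_rt_ms is not None:
        brt = df.groupby(["participant_id", "block_index"],
                         observed=True)["rt_ms"].mean()
        drop_pids |= set(brt[brt > rules.block_max_mean_rt_ms]
                         .index.get_level_values(0))
    report["participants_excluded"] = len(drop_pids)
    excluded = excluded | df["participant_id"].isin(drop_pids).to_numpy()

    kept = df[~excluded].reset_index(drop=True)
    report["n_excluded_trials"] = int(excluded.sum())
    report["retained_fraction"] = (float(len(kept) / len(df)) if len(df)
                                   else 1.0)
    meta = dict(dataset.metadata)
    meta.setdefault("filters_applied", []).append(
        {k: v for k, v in report.items()})
    return TrialDataset(kept, meta), report


def empirical_lower_cutoff(dataset: TrialDataset, bin_ms: float = 10.0,
                           alpha: float = 0.05, min_trials: int = 10) -> float:
    """Lowest RT at which pooled accuracy is reliably above chance.

    Scans fixed-width RT bins upward and returns the lower edge of the
    first bin (with at least ``min_trials`` pooled trials) whose accuracy
    exceeds 0.5 by a one-sided binomial test at level ``alpha``.
    Accuracy is pooled across participants.
    """
    df = dataset.records
    if "correct" not in df.columns or df["correct"].isna().all():
        raise RequirementError(
            "empirical lower cutoff requires accuracy data")
    rt = df["rt_ms"].to_numpy(dtype=float)
    correct = df["correct"].to_numpy(dtype=bool)
    edges = np.arange(np.floor(rt.min() / bin_ms) * bin_ms,
                      rt.max() + bin_ms, bin_ms)
    for lo in edges:
        in_bin = (rt >= lo) & (rt < lo + bin_ms)
        n = int(in_bin.sum())
        if n < min_trials:
            continue
        k = int(correct[in_bin].sum())
        if binomtest(k, n, 0.5, alternative="greater").pvalue < alpha:
            return float(lo)
    raise DegenerateInputError(
        "no RT bin with above-chance accuracy; cannot set empirical cutoff")


def _pair_d(df: pd.DataFrame, blocks: tuple, label: str) -> tuple[float, int]:
    sub = df[df["block_index"].isin(blocks)]
    inc = sub.loc[sub["compatibility"] == "incompatible", "rt_ms"]
    com = sub.loc[sub["compatibility"] == "compatible", "rt_ms"]
    if len(inc) < 2 or len(com) < 2:
        raise DegenerateInputError(
            f"empty or near-empty cell after filtering in the {label} pair "
            f"(blocks {blocks}): {len(com)} compatible / {len(inc)} "
            f"incompatible trials")
    sd = sub["rt_ms"].std(ddof=1)
    if sd == 0:
        raise DegenerateInputError(f"zero RT SD in the {label} pair")
    return float((inc.mean() - com.mean()) / sd), len(sub)


def d_score(trials: TrialDataset, rules: Optional[FilterRules] = None
            ) -> DScoreResult:
    """Improved-algorithm D-score for a single participant's trials.

    Computes one standardized difference per block pair (practice pair of
    20-trial blocks; test pair of 40-trial blocks), each as
    ``(mean incompatible - mean compatible) / SD over all included trials
    of both blocks in the pair``, then averages the two subscores.
    ``mean_diff_ms`` is the raw incompatible-compatible difference over all
    dual-stimulus trials.
    """
    if trials.records["participant_id"].nunique() != 1:
        raise StructuralError(
            "d_score expects a single participant's trials; use "
            "score_dataset for a whole dataset")
    report: dict = {}
    if rules is not None:
        trials, report = apply_filters(trials, rules)
    dual = trials.dual_trials()
    for pair in (PRACTICE_BLOCKS, TEST_BLOCKS):
        if not set(pair) & set(dual["block_index"].unique()):
            raise DegenerateInputError(
                f"missing dual-stimulus blocks {pair}")
    d_prac, n_prac = _pair_d(dual, PRACTICE_BLOCKS, "practice")
    d_test, n_test = _pair_d(dual, TEST_BLOCKS, "test")
    inc = dual.loc[dual["compatibility"] == "incompatible", "rt_ms"]
    com = dual.loc[dual["compatibility"] == "compatible", "rt_ms"]
    return DScoreResult(
        d_practice=d_prac, d_test=d_test,
        d_overall=(d_prac + d_test) / 2.0,
        mean_diff_ms=float(inc.mean() - com.mean()),
        n_trials_used=n_prac + n_test,
        exclusion_report=report)


def score_dataset(dataset: TrialDataset, rules: Optional[FilterRules] = None,
                  by_iat_type: bool = False) -> pd.DataFrame:
    """D-scores for every participant; one row per participant (and type).

    Participants whose filtered data leave an empty cell are skipped with
    a note in the ``error`` column rather than aborting the batch.
    """
    if rules is not None:
        dataset, _ = apply_filters(dataset, rules)
    keys = ["participant_id"] + (["iat_type"] if by_iat_type else [])
    rows = []
    for key, g in dataset.records.groupby(keys, observed=True):
        key = key if isinstance(key, tuple) else (key,)
        sub = TrialDataset(g.reset_index(drop=True))
        row = dict(zip(keys, key))
        order = g["condition_order"].iloc[0]
        row["condition_order"] = order
        try:
            res = d_score(sub, rules=None)
            row.update(d_practice=res.d_practice, d_test=res.d_test,
                       d_overall=res.d_overall,
                       mean_diff_ms=res.mean_diff_ms,
                       n_trials_used=res.n_trials_used)
        except DegenerateInputError as err:
            row["error"] = str(err)
        rows.append(row)
    return pd.DataFrame(rows)


def effective_trial_weights(n_practice: int, n_test: int) -> float:
    """Per-trial influence ratio early:late under equal subscore averaging.

    With subscores from a 20-trial and a 40-trial pair averaged with equal
    weight, each practice trial carries ``(1/n_practice)/(1/n_test)`` times
    the influence of a test trial: 2.0 for the standard 20/40 schedule.
    """
    if n_practice <= 0 or n_test <= 0:
        raise ParameterError("block lengths must be positive")
    return (1.0 / n_practice) / (1.0 / n_test)
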