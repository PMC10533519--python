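"""Filtering dialects and the improved D-score algorithm."""

import numpy as np
import pandas as pd
import pytest

from iatdyn.data_io import TrialDataset
from iatdyn.errors import (DegenerateInputError, ParameterError,
                           RequirementError)
from iatdyn.scoring import (FilterRules, STUDY1_PRESET, apply_filters,
                            d_score, effective_trial_weights,
                            empirical_lower_cutoff, score_dataset)
from iatdyn.synthetic_data import SyntheticConfig, simulate_iat


def participant_trials(practice_inc, practice_com, test_inc, test_com,
                       pid="p1"):
    """Build one participant's dual-stimulus trials from RT lists."""
    rows = []
    run_specs = [
        (1, "compatible", {3: practice_com, 4: test_com}),
        (2, "incompatible", {6: practice_inc, 7: test_inc}),
    ]
    for run, compat, blocks in run_specs:
        t = 0
        for blk, rts in blocks.items():
            for rt in rts:
                t += 1
                rows.append({
                    "participant_id": pid, "iat_type": "good_bad",
                    "block_index": blk, "run_index": run, "trial_index": t,
                    "compatibility": compat, "rt_ms": float(rt),
                    "correct": True,
                    "condition_order": "compatible_first"})
    return TrialDataset(pd.DataFrame(rows))


TOY = dict(practice_inc=[900, 1000], practice_com=[700, 800],
           test_inc=[850, 950, 900, 1000], test_com=[650, 750, 700, 800])


def test_d_score_matches_hand_computation():
    ds = participant_trials(**TOY)
    res = d_score(ds)
    # independent hand computation with plain numpy
    prac = np.array([900, 1000, 700, 800], dtype=float)
    test = np.array([850, 950, 900, 1000, 650, 750, 700, 800], dtype=float)
    d_prac = (np.mean([900, 1000]) - np.mean([700, 800])) / prac.std(ddof=1)
    d_test = (np.mean([850, 950, 900, 1000])
              - np.mean([650, 750, 700, 800])) / test.std(ddof=1)
    assert res.d_practice == pytest.approx(d_prac, abs=1e-12)
    assert res.d_test == pytest.approx(d_test, abs=1e-12)
    assert res.d_overall == pytest.approx((d_prac + d_test) / 2, abs=1e-12)
    assert res.mean_diff_ms == pytest.approx(
        np.mean([900, 1000, 850, 950, 900, 1000])
        - np.mean([700, 800, 650, 750, 700, 800]), abs=1e-12)
    assert res.n_trials_used == 12


def test_d_score_zero_under_identical_distributions():
    ds = participant_trials(practice_inc=[700, 800], practice_com=[700, 800],
                            test_inc=[650, 750, 700, 800],
                            test_com=[650, 750, 700, 800])
    assert d_score(ds).d_overall == pytest.approx(0.0, abs=1e-12)


def test_d_score_scale_free():
    base = d_score(participant_trials(**TOY))
    scaled = d_score(participant_trials(
        **{k: [3 * v for v in vals] for k, vals in TOY.items()}))
    assert scaled.d_overall == pytest.approx(base.d_overall, abs=1e-12)
    assert scaled.mean_diff_ms == pytest.approx(3 * base.mean_diff_ms,
                                                abs=1e-9)


def test_d_score_invariant_to_trial_order():
    ds = participant_trials(**TOY)
    shuffled = TrialDataset(
        ds.records.sample(frac=1.0, random_state=4).reset_index(drop=True))
    assert d_score(shuffled).d_overall == pytest.approx(
        d_score(ds).d_overall, abs=1e-12)


def test_d_score_empty_cell_is_named_error():
    ds = participant_trials(**TOY)
    dropped = TrialDataset(
        ds.records[ds.records["block_index"] != 6].reset_index(drop=True))
    with pytest.raises(DegenerateInputError, match="practice"):
        d_score(dropped)


def test_filters_count_per_rule(small_dataset):
    df = small_dataset.records.copy()
    df.loc[df.index[0], "rt_ms"] = 2500.0
    ds = TrialDataset(df)
    rules = FilterRules(lower_rt_ms=0.0, upper_rt_ms=2000.0,
                        drop_incorrect=False,
                        participant_min_accuracy=None,
                        participant_max_out_of_window=None)
    filtered, report = apply_filters(ds, rules)
    assert report["rt_above_upper"] >= 1
    assert len(filtered) == len(ds) - report["n_excluded_trials"]


def test_low_accuracy_participant_fully_removed(small_dataset):
    df = small_dataset.records.copy()
    victim = df["participant_id"].iloc[0]
    df.loc[df["participant_id"] == victim, "correct"] = \
        np.arange((df["participant_id"] == victim).sum()) % 4 != 0  # 75%
    ds = TrialDataset(df)
    rules = FilterRules(lower_rt_ms=0.0, upper_rt_ms=np.inf,
                        drop_incorrect=False, participant_min_accuracy=0.8,
                        participant_max_out_of_window=None)
    filtered, report = apply_filters(ds, rules)
    assert victim not in filtered.records["participant_id"].values
    assert report["participants_excluded"] == 1


def test_vacuous_rules_are_identity(small_dataset):
    rules = FilterRules(lower_rt_ms=0.0, upper_rt_ms=np.inf,
                        drop_incorrect=False, participant_min_accuracy=None,
                        participant_max_out_of_window=None)
    filtered, report = apply_filters(small_dataset, rules)
    assert len(filtered) == len(small_dataset)
    assert report["retained_fraction"] == 1.0


def test_study1_preset_block_rules():
    cfg = SyntheticConfig(n_participants=6, seed=4)
    ds, _ = simulate_iat(cfg)
    df = ds.records.copy()
    slow = df["participant_id"].iloc[0]
    df.loc[df["participant_id"] == slow, "rt_ms"] += 1500.0
    filtered, report = apply_filters(TrialDataset(df), STUDY1_PRESET)
    assert slow not in filtered.records["participant_id"].values


def test_filter_then_score_equals_score_with_rules(small_dataset):
    rules = FilterRules()
    pid = small_dataset.participants[0]
    one = small_dataset.for_participant(pid)
    direct = d_score(one, rules=rules)
    pre, _ = apply_filters(one, rules)
    indirect = d_score(pre)
    assert direct.d_overall == pytest.approx(indirect.d_overall, abs=1e-12)


def test_empirical_cutoff_finds_accuracy_step():
    rng = np.random.default_rng(6)
    n = 3000
    rt = rng.uniform(100, 600, n)
    correct = np.where(rt < 300, rng.random(n) < 0.5, rng.random(n) < 0.95)
    df = pd.DataFrame({
        "participant_id": "p1", "iat_type": "good_bad", "block_index": 3,
        "run_index": 1, "trial_index": np.arange(1, n + 1),
        "compatibility": "compatible", "rt_ms": rt, "correct": correct,
        "condition_order": "compatible_first"})
    cutoff = empirical_lower_cutoff(TrialDataset(df), bin_ms=10.0,
                                    alpha=0.001)
    assert cutoff == 300.0


def test_empirical_cutoff_boundary_and_sentinel():
    # strict alpha: the bin scan involves ~40 tests, so a lenient level
    # would produce false above-chance bins on pure-chance data
    rng = np.random.default_rng(1)
    n = 4000
    base = {"participant_id": "p1", "iat_type": "good_bad",
            "block_index": 3, "run_index": 1,
            "trial_index": np.arange(1, n + 1),
            "compatibility": "compatible",
            "condition_order": "compatible_first"}
    good = pd.DataFrame({**base, "rt_ms": rng.uniform(400, 800, n),
                         "correct": rng.random(n) < 0.95})
    assert empirical_lower_cutoff(TrialDataset(good), alpha=1e-4) == 400.0
    chance = pd.DataFrame({**base, "rt_ms": rng.uniform(400, 800, n),
                           "correct": rng.random(n) < 0.5})
    with pytest.raises(DegenerateInputError):
        empirical_lower_cutoff(TrialDataset(chance), alpha=1e-4)


def test_empirical_cutoff_requires_accuracy(small_dataset):
    df = small_dataset.records.drop(columns=["correct"])
    df["correct"] = np.nan
    with pytest.raises(RequirementError):
        empirical_lower_cutoff(TrialDataset(df))


def test_mean_diff_consistent_at_large_n():
    cfg = SyntheticConfig(
        n_participants=1, seed=8,
        block_lengths=(20, 20, 2000, 4000, 40, 2000, 4000),
        sd_log_start=0.0, sd_log_asym=0.0, sd_log_rate=0.0,
        sd_log_gauss_mean=0.0, sd_compat_log_start=0.0,
        sd_compat_log_asym=0.0, carryover_log_asym=0.0)
    ds, truth = simulate_iat(cfg)
    res = d_score(ds.for_participant(ds.participants[0]))
    expected = truth.indices["overall_diff_ms"].iloc[0]
    assert res.mean_diff_ms == pytest.approx(expected, abs=15.0)


@pytest.mark.parametrize("n_prac,n_test,ratio",
                         [(20, 40, 2.0), (30, 30, 1.0), (10, 40, 4.0)])
def test_effective_trial_weights(n_prac, n_test, ratio):
    assert effective_trial_weights(n_prac, n_test) == pytest.approx(ratio)


def test_effective_trial_weights_domain():
    with pytest.raises(ParameterError):
        effective_trial_weights(0, 40)


def test_score_dataset_one_row_per_participant(small_dataset):
    out = score_dataset(small_dataset)
    assert len(out) == len(small_dataset.participants)
    assert {"d_practice", "d_test", "d_overall",
            "mean_diff_ms"} <= set(out.columns)
    assert out["d_overall"].notna().all()
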