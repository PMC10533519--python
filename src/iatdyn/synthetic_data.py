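"""Synthetic trial-level IAT data with known ground truth.

The generator emulates the standard 7-block IAT: two dual-stimulus runs of
60 trials (a 20-trial block followed by a 40-trial block per key pairing),
counterbalanced pairing order across participants.  Response times are
ex-Gaussian with a trial-constant Gaussian component and an exponential
mean that follows a saturating trajectory; compatibility, pairing order
(as a second-run carry-over), IAT type and optional learning-condition
contrasts act on the log-scale trajectory parameters.  External behavioural
measures are generated from stated linear links to the latent per-person
trajectory indices, which makes every downstream analysis testable against
configured truth.

Default population values are realistic for online race-IAT data: the log
Gaussian mean, log start, log asymptote and log rate population intercepts
are 6.161, 5.878, 5.112 and 2.451 (ms / ms / ms / trials after exp), the
compatibility effects on log start/asymptote/rate are 0.374 / 0.342 /
0.658, and the word-vs-face effect on the log Gaussian mean is 0.127.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .data_io import ExternalMeasuresTable, TrialDataset
from .errors import ParameterError, RequirementError
from .exgauss import TrajectoryParams, _tau_trajectory

__all__ = ["SyntheticConfig", "GroundTruth", "simulate_iat",
           "simulate_externals", "fig1_pair"]


def _default_external_links() -> dict:
    # Rate-linked behaviour: faster change in RT differences relates to the
    # interviewer-facing outcomes; asymptotic (persistent) differences
    # interact with internal motivation.
    return {
        "seeming_racist": {"rate": -0.25, "asym_diff:ims": 0.3},
        "seating_distance_cm": {"rate:ems:interviewer_race": 0.6,
                                "rate:ems": -0.35},
    }


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic IAT generator (all effects on log scales).

    The defaults are the study conditions the analyses assume: 60
    participants, two runs of 60 dual-stimulus trials per IAT type,
    population parameters at the scale of real online race-IAT fits, and
    moderate person-level heterogeneity.
    """

    n_participants: int = 60
    seed: int = 0
    #: trial counts of the 7 blocks; 3/4/6/7 are the dual-stimulus blocks
    block_lengths: tuple = (20, 20, 20, 40, 40, 20, 40)
    iat_types: tuple = ("good_bad",)

    # population means (log ms; log trials for rate)
    mean_log_gauss_mean: float = 6.161
    mean_log_start: float = 5.878
    mean_log_asym: float = 5.112
    mean_log_rate: float = 2.451
    gauss_sd_ms: float = 50.0
    word_vs_face_log_gauss_mean: float = 0.127

    # fixed effects (applied through +/-0.5 zero-centered codes)
    compat_log_start: float = 0.374
    compat_log_asym: float = 0.342
    compat_log_rate: float = 0.658
    #: carry-over: shift applied to the second run's log asymptote
    carryover_log_asym: float = -0.15
    iat_type_log_start: float = -0.28
    iat_type_log_asym: float = 0.106
    iat_type_log_rate: float = -0.351
    iat_type_compat_log_start: float = -0.165
    iat_type_compat_log_asym: float = -0.243

    # participant random-effect SDs (log scale)
    sd_log_gauss_mean: float = 0.10
    sd_log_start: float = 0.25
    sd_log_asym: float = 0.25
    sd_log_rate: float = 0.30
    sd_compat_log_start: float = 0.15
    sd_compat_log_asym: float = 0.15

    #: static truth: tau is trial-constant (start tied to asymptote cell
    #: by cell), the generating counterpart of the no-change null model
    static: bool = False

    # accuracy model: chance below the floor, near-ceiling above
    base_accuracy: float = 0.95
    chance_floor_ms: float = 300.0
    accuracy_width_ms: float = 10.0

    # optional learning-condition arm (reference level first)
    conditions: Optional[tuple] = None
    n_experiments: int = 1
    condition_compat_effects: dict = field(default_factory=dict)

    # external-measure links: outcome -> {component[:component...]: coef}
    external_links: dict = field(default_factory=_default_external_links)
    external_noise_sd: float = 0.6

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ParameterError("n_participants must be >= 1")
        if self.seed is None:
            raise ParameterError("seed is mandatory")
        if len(self.block_lengths) != 7 or any(b <= 0 for b in self.block_lengths):
            raise ParameterError("block_lengths must be 7 positive counts")
        for name in ("gauss_sd_ms", "sd_log_gauss_mean", "sd_log_start",
                     "sd_log_asym", "sd_log_rate", "sd_compat_log_start",
                     "sd_compat_log_asym", "external_noise_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if not 0.5 <= self.base_accuracy <= 1.0:
            raise ParameterError("base_accuracy must be in [0.5, 1]")


@dataclass
class GroundTruth:
    """Everything the generator knows: the recovery oracle."""

    fixed_effects: dict
    participants: pd.DataFrame
    #: per (participant, iat_type, compatibility) trajectory on the ms scale
    trajectories: pd.DataFrame
    #: per-participant true indices: start/asym/overall diffs (ms), rate (trials)
    indices: pd.DataFrame
    external_links: dict


_RUN_BLOCKS = {1: (3, 4), 2: (6, 7)}

_LINK_COMPONENTS = ("start_diff", "asym_diff", "rate", "overall",
                    "ims", "ems", "interviewer_race", "gender", "age")


def _cell_logparams(cfg: SyntheticConfig, person: pd.Series, type_code: float,
                    c: float, run: int, cond: Optional[str]) -> tuple:
    """Log start/rate/asym for one (participant, iat_type, compat, run) cell."""
    two_types = type_code != 0.0
    ls = (cfg.mean_log_start + person["b_start"]
          + c * (cfg.compat_log_start + person["b_compat_start"]))
    la = (cfg.mean_log_asym + person["b_asym"]
          + c * (cfg.compat_log_asym + person["b_compat_asym"]))
    lr = cfg.mean_log_rate + person["b_rate"] + c * cfg.compat_log_rate
    if two_types:
        ls += type_code * cfg.iat_type_log_start \
            + type_code * c * cfg.iat_type_compat_log_start
        la += type_code * cfg.iat_type_log_asym \
            + type_code * c * cfg.iat_type_compat_log_asym
        lr += type_code * cfg.iat_type_log_rate
    if run == 2:
        la += cfg.carryover_log_asym
    if cond is not None and cfg.conditions and cond != cfg.conditions[0]:
        eff = cfg.condition_compat_effects.get(cond, {})
        ls += c * eff.get("log_start", 0.0)
        la += c * eff.get("log_asym", 0.0)
        lr += c * eff.get("log_rate", 0.0)
    if cfg.static:
        ls = la  # start tied to asymptote: no change over trials
    return ls, lr, la


def simulate_iat(config: SyntheticConfig) -> tuple[TrialDataset, GroundTruth]:
    """Generate a full synthetic IAT trial dataset and its ground truth.

    Pairing order is counterbalanced (even participant index -> compatible
    pairing first).  Per trial the RT is drawn as
    ``Normal(mu, gauss_sd) + Exponential(tau(t))`` with ``tau`` following
    the participant/cell trajectory; accuracy follows a logistic-in-RT
    model with a chance floor below ``chance_floor_ms``.  Fully
    reproducible from ``config.seed``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_participants
    n_types = len(cfg.iat_types)
    if n_types not in (1, 2):
        raise ParameterError("iat_types must name 1 or 2 IAT types")

    pids = [f"p{i:04d}" for i in range(n)]
    orders = ["compatible_first" if i % 2 == 0 else "incompatible_first"
              for i in range(n)]
    persons = pd.DataFrame({
        "participant_id": pids,
        "condition_order": orders,
        "b_gauss_mean": rng.normal(0, cfg.sd_log_gauss_mean, n),
        "b_start": rng.normal(0, cfg.sd_log_start, n),
        "b_rate": rng.normal(0, cfg.sd_log_rate, n),
        "b_asym": rng.normal(0, cfg.sd_log_asym, n),
        "b_compat_start": rng.normal(0, cfg.sd_compat_log_start, n),
        "b_compat_asym": rng.normal(0, cfg.sd_compat_log_asym, n),
    })
    persons["gender"] = rng.choice([-0.5, 0.5], size=n)
    persons["age"] = rng.normal(0.0, 1.0, size=n)
    if cfg.conditions:
        persons["condition"] = [cfg.conditions[i % len(cfg.conditions)]
                                for i in range(n)]
        persons["experiment_id"] = [f"e{i % cfg.n_experiments}"
                                    for i in range(n)]

    n_prac, n_test = cfg.block_lengths[2], cfg.block_lengths[3]
    run_len = n_prac + n_test
    t_run = np.arange(1, run_len + 1, dtype=float)

    rows = []
    traj_rows = []
    for i, pid in enumerate(pids):
        person = persons.iloc[i]
        cond = person["condition"] if cfg.conditions else None
        for itype in cfg.iat_types:
            type_code = 0.0 if n_types == 1 else \
                (0.5 if itype == cfg.iat_types[0] else -0.5)
            for run in (1, 2):
                first_compat = person["condition_order"] == "compatible_first"
                compat = ("compatible" if (run == 1) == first_compat
                          else "incompatible")
                c = 0.5 if compat == "incompatible" else -0.5
                ls, lr, la = _cell_logparams(cfg, person, type_code, c, run, cond)
                start, rate, asym = np.exp(ls), np.exp(lr), np.exp(la)
                tau_t = _tau_trajectory(t_run, start, rate, asym)
                stim = np.where(t_run % 2 == 1, "word", "face")
                stim_code = np.where(stim == "word", 0.5, -0.5)
                mu = np.exp(cfg.mean_log_gauss_mean + person["b_gauss_mean"]
                            + cfg.word_vs_face_log_gauss_mean * stim_code)
                rt = rng.normal(mu, cfg.gauss_sd_ms) + rng.exponential(tau_t)
                while np.any(rt <= 0):  # essentially never at these scales
                    bad = rt <= 0
                    rt[bad] = (rng.normal(mu if np.isscalar(mu) else mu[bad],
                                          cfg.gauss_sd_ms)
                               + rng.exponential(tau_t[bad]))
                p_corr = 0.5 + (cfg.base_accuracy - 0.5) / (
                    1.0 + np.exp(-(rt - cfg.chance_floor_ms)
                                 / cfg.accuracy_width_ms))
                correct = rng.random(run_len) < p_corr
                blocks = np.where(t_run <= n_prac, _RUN_BLOCKS[run][0],
                                  _RUN_BLOCKS[run][1])
                chunk = pd.DataFrame({
                    "participant_id": pid,
                    "iat_type": itype,
                    "block_index": blocks,
                    "run_index": run,
                    "trial_index": t_run.astype(int),
                    "compatibility": compat,
                    "stimulus_class": stim,
                    "rt_ms": rt,
                    "correct": correct,
                    "condition_order": person["condition_order"],
                })
                if cfg.conditions:
                    chunk["condition"] = cond
                    chunk["experiment_id"] = person["experiment_id"]
                    chunk["gender"] = person["gender"]
                    chunk["age"] = person["age"]
                rows.append(chunk)
                if run == 1:
                    traj_rows.append({
                        "participant_id": pid, "iat_type": itype,
                        "compatibility": compat, "start_ms": start,
                        "rate_trials": rate, "asym_ms": asym})
                    # also record the opposite pairing at first-run footing
                    c2 = -c
                    ls2, lr2, la2 = _cell_logparams(
                        cfg, person, type_code, c2, 1, cond)
                    traj_rows.append({
                        "participant_id": pid, "iat_type": itype,
                        "compatibility": ("incompatible" if c2 > 0
                                          else "compatible"),
                        "start_ms": np.exp(ls2), "rate_trials": np.exp(lr2),
                        "asym_ms": np.exp(la2)})

    records = pd.concat(rows, ignore_index=True)
    trajectories = pd.DataFrame(traj_rows)

    indices = _true_indices(cfg, persons, run_len)

    # Model-scale truth.  Under centered +/-0.5 codes the second-run
    # carry-over gamma*1[run=2] decomposes exactly as
    # gamma/2 - 2*gamma*(compat_code * order_code), i.e. an intercept
    # shift plus a compatibility:order interaction on the log asymptote.
    g = cfg.carryover_log_asym
    fixed = {
        "log_gauss_mean.intercept": cfg.mean_log_gauss_mean,
        "log_gauss_mean.word_vs_face": cfg.word_vs_face_log_gauss_mean,
        "log_start.intercept": cfg.mean_log_start,
        "log_start.compatibility": cfg.compat_log_start,
        "log_start.order": 0.0,
        "log_start.compatibility:order": 0.0,
        "log_rate.intercept": cfg.mean_log_rate,
        "log_rate.compatibility": cfg.compat_log_rate,
        "log_rate.order": 0.0,
        "log_rate.compatibility:order": 0.0,
        "log_asym.intercept": cfg.mean_log_asym + g / 2.0,
        "log_asym.compatibility": cfg.compat_log_asym,
        "log_asym.order": 0.0,
        "log_asym.compatibility:order": -2.0 * g,
        "log_asym.carryover_run2": g,
    }
    truth = GroundTruth(fixed_effects=fixed, participants=persons,
                        trajectories=trajectories, indices=indices,
                        external_links=dict(cfg.external_links))
    meta = {"source": "iatdyn.synthetic_data.simulate_iat", "seed": cfg.seed,
            "n_participants": n, "iat_types": list(cfg.iat_types)}
    return TrialDataset(records, meta), truth


def _true_indices(cfg: SyntheticConfig, persons: pd.DataFrame,
                  run_len: int) -> pd.DataFrame:
    """Per-participant true indices at IAT-type code 0, first-run footing."""
    t = np.arange(1, run_len + 1, dtype=float)
    out = []
    for _, person in persons.iterrows():
        cells = {}
        for c, lab in ((0.5, "incompatible"), (-0.5, "compatible")):
            ls, lr, la = _cell_logparams(cfg, person, 0.0, c, 1, None)
            cells[lab] = (np.exp(ls), np.exp(lr), np.exp(la))
        s_i, r_i, a_i = cells["incompatible"]
        s_c, r_c, a_c = cells["compatible"]
        diff_t = (_tau_trajectory(t, s_i, r_i, a_i)
                  - _tau_trajectory(t, s_c, r_c, a_c))
        out.append({
            "participant_id": person["participant_id"],
            "start_diff_ms": s_i - s_c,
            "asym_diff_ms": a_i - a_c,
            "rate_trials": np.exp(cfg.mean_log_rate + person["b_rate"]),
            "overall_diff_ms": float(np.mean(diff_t)),
        })
    return pd.DataFrame(out)


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = np.std(v, ddof=1)
    return (v - np.mean(v)) / sd if sd > 0 else np.zeros_like(v)


def simulate_externals(truth: GroundTruth, config: SyntheticConfig
                       ) -> ExternalMeasuresTable:
    """Generate participant-level external measures from the ground truth.

    Each configured outcome is a linear combination of z-scored components
    (true latent indices, IMS/EMS, interviewer race and their products)
    plus Gaussian noise, then mapped onto its instrument scale (1-5 for
    the seeming-racist rating, cm for seating distance).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed + 104729)  # independent stream
    idx = truth.indices.reset_index(drop=True)
    n = len(idx)
    ims = np.clip(rng.normal(6.5, 1.5, n), 1.0, 9.0)
    ems = np.clip(rng.normal(5.0, 1.8, n), 1.0, 9.0)
    race = rng.choice(["white", "black"], size=n)
    sex = rng.choice(["male", "female"], size=n)
    persons = truth.participants.reset_index(drop=True)

    comp = {
        "start_diff": _standardize(idx["start_diff_ms"].to_numpy()),
        "asym_diff": _standardize(idx["asym_diff_ms"].to_numpy()),
        "rate": _standardize(idx["rate_trials"].to_numpy()),
        "overall": _standardize(idx["overall_diff_ms"].to_numpy()),
        "ims": _standardize(ims),
        "ems": _standardize(ems),
        "interviewer_race": np.where(race == "white", 0.5, -0.5),
        "gender": persons["gender"].to_numpy(),
        "age": _standardize(persons["age"].to_numpy()),
    }

    def latent(links: dict) -> np.ndarray:
        z = np.zeros(n)
        for term, coef in links.items():
            parts = term.split(":")
            for p in parts:
                if p not in comp:
                    raise RequirementError(
                        f"external link names unknown component {p!r}; "
                        f"known: {sorted(comp)}")
            z += coef * np.prod([comp[p] for p in parts], axis=0)
        return z + rng.normal(0, cfg.external_noise_sd, n)

    z_seem = latent(cfg.external_links.get("seeming_racist", {}))
    z_seat = latent(cfg.external_links.get("seating_distance_cm", {}))
    table = pd.DataFrame({
        "participant_id": idx["participant_id"],
        "ims": ims,
        "ems": ems,
        "interviewer_race": race,
        "interviewer_sex": sex,
        "seating_distance_cm": np.maximum(20.0, 80.0 + 15.0 * z_seat),
        "seeming_racist": np.clip(3.0 + 0.7 * z_seem, 1.0, 5.0),
        "gender": persons["gender"],
        "age": 19.0 + 2.0 * persons["age"],
    })
    return ExternalMeasuresTable(table)


def _mean_weight(rate: float, n_trials: int) -> float:
    """Mean of 2**(-(t-1)/rate) over t = 1..n_trials."""
    t = np.arange(1, n_trials + 1, dtype=float)
    return float(np.mean(np.exp2(-(t - 1.0) / rate)))


def fig1_pair(mean_diff_ms: float = 82.0, mu_ms: float = 450.0,
              n_trials: int = 60) -> tuple[TrialDataset, GroundTruth]:
    """Two artificial participants with identical aggregate IAT effects.

    Participant 1 starts with a large compatibility difference in the
    exponential mean that decays to near zero; participant 2 starts with a
    smaller difference, changes fast, and levels off at a larger final
    difference.  The start differences are calibrated analytically so both
    participants' aggregate mean RT differences equal ``mean_diff_ms``
    exactly.  Responses are noise-free expected RTs (``mu + tau(t)``),
    making the demonstration deterministic.
    """
    # (asym difference ms, rate trials) for the two demonstration profiles
    profiles = [(2.0, 10.0), (75.0, 3.0)]
    base = {"start_ms": 250.0, "asym_ms": 150.0}

    rows, traj_rows, idx_rows = [], [], []
    for k, (dasym, rate) in enumerate(profiles, start=1):
        wbar = _mean_weight(rate, n_trials)
        dstart = dasym + (mean_diff_ms - dasym) / wbar
        pid = f"fig1_p{k}"
        comp = TrajectoryParams(base["start_ms"], rate, base["asym_ms"])
        incomp = TrajectoryParams(base["start_ms"] + dstart, rate,
                                  base["asym_ms"] + dasym)
        n_prac = 20
        t = np.arange(1, n_trials + 1, dtype=float)
        for run, (traj, compat) in enumerate(
                [(comp, "compatible"), (incomp, "incompatible")], start=1):
            tau_t = _tau_trajectory(t, traj.start_ms, traj.rate_trials,
                                    traj.asym_ms)
            rows.append(pd.DataFrame({
                "participant_id": pid,
                "iat_type": "generic",
                "block_index": np.where(t <= n_prac, _RUN_BLOCKS[run][0],
                                        _RUN_BLOCKS[run][1]),
                "run_index": run,
                "trial_index": t.astype(int),
                "compatibility": compat,
                "stimulus_class": np.where(t % 2 == 1, "word", "face"),
                "rt_ms": mu_ms + tau_t,
                "correct": True,
                "condition_order": "compatible_first",
            }))
            traj_rows.append({"participant_id": pid, "iat_type": "generic",
                              "compatibility": compat,
                              "start_ms": traj.start_ms,
                              "rate_trials": traj.rate_trials,
                              "asym_ms": traj.asym_ms})
        idx_rows.append({"participant_id": pid, "start_diff_ms": dstart,
                         "asym_diff_ms": dasym, "rate_trials": rate,
                         "overall_diff_ms": mean_diff_ms})

    records = pd.concat(rows, ignore_index=True)
    truth = GroundTruth(
        fixed_effects={},
        participants=pd.DataFrame({"participant_id": [r["participant_id"]
                                                      for r in idx_rows]}),
        trajectories=pd.DataFrame(traj_rows),
        indices=pd.DataFrame(idx_rows),
        external_links={})
    meta = {"source": "iatdyn.synthetic_data.fig1_pair",
            "mean_diff_ms": mean_diff_ms}
    return TrialDataset(records, meta), truth
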