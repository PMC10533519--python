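"""Trial-level and participant-level data model, CSV round-trip, validation.

The universal input is a long-format trial table for the standard 7-block
IAT: blocks 3, 4, 6 and 7 carry dual-stimulus trials (a 20-trial and a
40-trial block per key pairing), blocks 1, 2 and 5 are single-stimulus
training.  Within one pairing ("run") the trial index counts continuously
1..60 across its 20- and 40-trial blocks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError, StructuralError

__all__ = [
    "TrialDataset",
    "ExternalMeasuresTable",
    "Violation",
    "read_trials",
    "write_trials",
    "read_externals",
    "write_externals",
    "validate",
    "DUAL_BLOCKS",
    "PRACTICE_BLOCKS",
    "TEST_BLOCKS",
]

DUAL_BLOCKS = (3, 4, 6, 7)
PRACTICE_BLOCKS = (3, 6)   # 20-trial dual blocks
TEST_BLOCKS = (4, 7)       # 40-trial dual blocks

IAT_TYPES = ("good_bad", "competent_incompetent", "generic")
COMPATIBILITIES = ("compatible", "incompatible")
ORDERS = ("compatible_first", "incompatible_first")

#: Columns every trial table must carry, in canonical on-disk order.
REQUIRED_COLUMNS = [
    "participant_id", "iat_type", "block_index", "run_index", "trial_index",
    "compatibility", "rt_ms", "correct", "condition_order",
]
#: Optional columns, preserved when present.
OPTIONAL_COLUMNS = ["stimulus_class", "condition", "experiment_id"]

_EXTERNAL_COLUMNS = [
    "participant_id", "ims", "ems", "interviewer_race", "interviewer_sex",
    "seating_distance_cm", "seeming_racist", "gender", "age",
]


@dataclass
class Violation:
    """One structural-invariant violation with the offending keys."""

    rule: str
    detail: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.rule}] {self.detail}"


@dataclass
class TrialDataset:
    """Long-format trial-level IAT observations plus provenance metadata."""

    records: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.records.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        if len(self.records) and not pd.api.types.is_numeric_dtype(self.records["rt_ms"]):
            raise SchemaError("rt_ms column is not numeric")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def participants(self) -> np.ndarray:
        return np.sort(self.records["participant_id"].unique())

    def dual_trials(self) -> pd.DataFrame:
        """Rows from the dual-stimulus blocks (3, 4, 6, 7)."""
        return self.records[self.records["block_index"].isin(DUAL_BLOCKS)]

    def for_participant(self, participant_id) -> "TrialDataset":
        sub = self.records[self.records["participant_id"] == participant_id]
        return TrialDataset(sub.reset_index(drop=True), dict(self.metadata))


@dataclass
class ExternalMeasuresTable:
    """One row per participant of external behavioural/survey measures."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if "participant_id" not in self.table.columns:
            raise SchemaError("missing required column(s): participant_id")
        if self.table["participant_id"].duplicated().any():
            dupes = self.table.loc[
                self.table["participant_id"].duplicated(), "participant_id"
            ].tolist()
            raise StructuralError(f"duplicate participant rows: {dupes}")
        for col, lo, hi in (("ims", 1, 9), ("ems", 1, 9), ("seeming_racist", 1, 5)):
            if col in self.table.columns:
                vals = pd.to_numeric(self.table[col], errors="coerce").dropna()
                if len(vals) and ((vals < lo) | (vals > hi)).any():
                    raise StructuralError(f"{col} outside its {lo}-{hi} scale bounds")

    def __len__(self) -> int:
        return len(self.table)


def _canonical_columns(df: pd.DataFrame) -> list[str]:
    extra = [c for c in OPTIONAL_COLUMNS if c in df.columns]
    trailing = [c for c in df.columns
                if c not in REQUIRED_COLUMNS and c not in extra]
    return REQUIRED_COLUMNS + extra + trailing


def read_trials(path, dialect: str = "standard") -> TrialDataset:
    """Read a long-format trial CSV into a validated :class:`TrialDataset`.

    Parameters
    ----------
    path : path-like
    dialect : str
        Only ``"standard"`` (UTF-8, comma, "." decimal) is defined.

    Raises
    ------
    SchemaError
        If a required column is missing or RT is non-numeric.
    StructuralError
        If the table violates a dataset invariant (see :func:`validate`).
    """
    if dialect != "standard":
        raise SchemaError(f"unknown trial CSV dialect: {dialect!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"trial CSV not found: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    rt = pd.to_numeric(df["rt_ms"], errors="coerce")
    bad = df.index[rt.isna() & df["rt_ms"].notna()]
    if len(bad):
        raise SchemaError(f"non-numeric rt_ms at row(s): {list(bad[:10])}")
    df["rt_ms"] = rt
    if "correct" in df.columns and df["correct"].dtype == object:
        df["correct"] = df["correct"].map(
            {"True": True, "False": False, True: True, False: False})
    meta_path = path.with_suffix(".meta.json")
    metadata = {}
    if meta_path.exists():
        metadata = json.loads(meta_path.read_text())
    metadata.setdefault("source", str(path))
    ds = TrialDataset(df, metadata)
    violations = validate(ds)
    if violations:
        lines = "; ".join(str(v) for v in violations[:5])
        raise StructuralError(
            f"{len(violations)} invariant violation(s), e.g. {lines}")
    return ds


def write_trials(dataset: TrialDataset, path) -> Path:
    """Write a trial dataset to CSV with deterministic column order.

    Floats use Python's shortest round-trip repr so that
    ``write -> read -> write`` is byte-identical.  A JSON metadata sidecar
    is written next to the CSV.
    """
    path = Path(path)
    cols = _canonical_columns(dataset.records)
    df = dataset.records.loc[:, cols]
    df.to_csv(path, index=False)
    if dataset.metadata:
        meta = {k: v for k, v in dataset.metadata.items()}
        path.with_suffix(".meta.json").write_text(
            json.dumps(meta, indent=1, sort_keys=True, default=str))
    return path


def read_externals(path) -> ExternalMeasuresTable:
    """Read the participant-level external measures CSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"externals CSV not found: {path}")
    return ExternalMeasuresTable(pd.read_csv(path))


def write_externals(table: ExternalMeasuresTable, path) -> Path:
    path = Path(path)
    lead = [c for c in _EXTERNAL_COLUMNS if c in table.table.columns]
    rest = [c for c in table.table.columns if c not in lead]
    table.table.loc[:, lead + rest].to_csv(path, index=False)
    return path


def validate(dataset: TrialDataset) -> list[Violation]:
    """Report every structural-invariant violation; empty list iff valid.

    Pure reporting operation: never mutates, deterministic.
    Rules checked:

    * ``dual_block`` — dual-stimulus trials only in blocks 3, 4, 6, 7
      (a trial with a non-null compatibility is dual-stimulus).
    * ``duplicate_key`` — (participant, iat_type, block, trial) unique.
    * ``consecutive_trials`` — within (participant, iat_type, run) the
      trial index runs 1, 2, ... without gaps.
    * ``block_compatibility`` — compatibility constant within a block and
      opposite between the two runs of one (participant, iat_type).
    * ``positive_rt`` — RTs strictly positive.
    * ``run_per_type`` — every participant has >= 1 run per iat_type
      present in the dataset.
    """
    df = dataset.records
    out: list[Violation] = []
    if not len(df):
        return out

    dual = df["compatibility"].notna()
    misplaced = df[dual & ~df["block_index"].isin(DUAL_BLOCKS)]
    for _, row in misplaced.iterrows():
        out.append(Violation(
            "dual_block",
            f"dual-stimulus trial outside blocks {DUAL_BLOCKS}: participant "
            f"{row['participant_id']}, block {row['block_index']}, "
            f"trial {row['trial_index']}"))

    key_cols = ["participant_id", "iat_type", "block_index", "trial_index"]
    dup = df[df.duplicated(key_cols, keep=False)]
    for key, _ in dup.groupby(key_cols, observed=True):
        out.append(Violation("duplicate_key", f"duplicate trial key {key}"))

    bad_rt = df[~(df["rt_ms"] > 0)]
    for _, row in bad_rt.iterrows():
        out.append(Violation(
            "positive_rt",
            f"non-positive RT {row['rt_ms']} for participant "
            f"{row['participant_id']}, block {row['block_index']}"))

    dual_df = df[dual]
    for (pid, itype, run), g in dual_df.groupby(
            ["participant_id", "iat_type", "run_index"], observed=True):
        idx = np.sort(g["trial_index"].to_numpy())
        expected = np.arange(1, len(idx) + 1)
        if not np.array_equal(idx, expected):
            out.append(Violation(
                "consecutive_trials",
                f"trial_index not consecutive from 1 for participant {pid}, "
                f"iat_type {itype}, run {run}"))
        comps = g.groupby("block_index", observed=True)["compatibility"].nunique()
        for blk, k in comps.items():
            if k > 1:
                out.append(Violation(
                    "block_compatibility",
                    f"mixed compatibility within block {blk} for "
                    f"participant {pid}, iat_type {itype}"))
    for (pid, itype), g in dual_df.groupby(
            ["participant_id", "iat_type"], observed=True):
        run_comp = g.groupby("run_index", observed=True)["compatibility"].agg(
            lambda s: s.iloc[0])
        if len(run_comp) == 2 and run_comp.nunique() == 1:
            out.append(Violation(
                "block_compatibility",
                f"the two runs share compatibility {run_comp.iloc[0]!r} for "
                f"participant {pid}, iat_type {itype}"))

    types_present = dual_df["iat_type"].dropna().unique()
    for pid, g in dual_df.groupby("participant_id", observed=True):
        missing_types = set(types_present) - set(g["iat_type"].unique())
        if missing_types:
            out.append(Violation(
                "run_per_type",
                f"participant {pid} has no run for iat_type(s) "
                f"{sorted(missing_types)}"))
    return out
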