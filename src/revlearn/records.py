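"""Trial records: the atomic unit of behavioural logs.

A :class:`TrialRecord` captures one completed trial — what was shown,
what was chosen, on which side, and whether the choice was reinforced.
Logs are exchanged as pandas DataFrames with the :data:`COLUMNS` schema
(one row per trial) and serialised as plain CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import pandas as pd

from .task import Side, TrialType

__all__ = ["TrialRecord", "COLUMNS", "records_to_frame", "frame_to_records", "validate_frame"]

COLUMNS = [
    "subject_id",
    "group_label",
    "session",
    "trial_index",
    "trial_type",
    "left_stim",
    "right_stim",
    "chosen_stim",
    "chosen_side",
    "reinforced",
]


@dataclass(frozen=True)
class TrialRecord:
    subject_id: str
    group_label: str
    session: int
    trial_index: int
    trial_type: TrialType
    left_stim: str
    right_stim: str
    chosen_stim: str
    chosen_side: Side
    reinforced: int

    def __post_init__(self) -> None:
        if self.chosen_stim not in (self.left_stim, self.right_stim):
            raise ValueError("chosen_stim not among presented stimuli")
        expected = Side.L if self.chosen_stim == self.left_stim else Side.R
        if self.chosen_side is not expected:
            raise ValueError("chosen_side inconsistent with chosen_stim")
        if self.reinforced not in (0, 1):
            raise ValueError("reinforced must be 0 or 1")


def records_to_frame(records: list[TrialRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = asdict(r)
        d["trial_type"] = r.trial_type.value
        d["chosen_side"] = r.chosen_side.value
        rows.append(d)
    return pd.DataFrame(rows, columns=COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[TrialRecord]:
    validate_frame(df)
    out = []
    for row in df.itertuples(index=False):
        out.append(
            TrialRecord(
                subject_id=str(row.subject_id),
                group_label=str(row.group_label),
                session=int(row.session),
                trial_index=int(row.trial_index),
                trial_type=TrialType(row.trial_type),
                left_stim=str(row.left_stim),
                right_stim=str(row.right_stim),
                chosen_stim=str(row.chosen_stim),
                chosen_side=Side(row.chosen_side),
                reinforced=int(row.reinforced),
            )
        )
    return out


def validate_frame(df: pd.DataFrame) -> None:
    """Row-level validation of a trial-log frame; raises with row numbers."""
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial log missing columns: {missing}")
    problems = []
    chosen_ok = (df["chosen_stim"] == df["left_stim"]) | (df["chosen_stim"] == df["right_stim"])
    for i in df.index[~chosen_ok]:
        problems.append(f"row {i}: chosen_stim not among presented stimuli")
    expected_side = pd.Series("R", index=df.index).where(df["chosen_stim"] != df["left_stim"], "L")
    side_ok = df["chosen_side"] == expected_side
    for i in df.index[chosen_ok & ~side_ok]:
        problems.append(f"row {i}: chosen_side inconsistent with chosen_stim")
    reinf_ok = df["reinforced"].isin([0, 1])
    for i in df.index[~reinf_ok]:
        problems.append(f"row {i}: reinforced must be 0 or 1")
    bad_type = ~df["trial_type"].isin([t.value for t in TrialType])
    for i in df.index[bad_type]:
        problems.append(f"row {i}: unknown trial_type {df.loc[i, 'trial_type']!r}")
    if problems:
        raise ValueError("invalid trial log:\n" + "\n".join(problems[:20]))
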