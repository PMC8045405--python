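"""Trial data input/output and the bundled everolimus dataset.

The on-disk format is one CSV row per patient with columns
``patient_id, schedule_id, dose_mg, interval_h, time_h, dlt``; the cycle
length lives in the design configuration, not in the data file.

The bundled dataset is the phase Ib everolimus trial in small-cell lung
cancer (weekly and daily schedules escalated in 21-day cycles): no DLT in 5
patients at 20 mg weekly, 4 DLT in 13 patients at 30 mg weekly, 2 DLT in 4
patients at 2.5 mg daily and 3 DLT in 6 patients at 5 mg daily, with every
DLT reported at day 15 of the cycle.
"""

from __future__ import annotations

from importlib import resources
from typing import Iterable

import numpy as np
import pandas as pd

from .models.blrm import DoseToxData
from .models.tite import SubjectEvent
from .pk import Regimen

__all__ = [
    "REQUIRED_COLUMNS",
    "load_trial_csv",
    "save_trial_csv",
    "to_subjects",
    "to_dose_tox",
    "load_everolimus",
    "everolimus_subjects",
    "everolimus_counts",
]

REQUIRED_COLUMNS = (
    "patient_id",
    "schedule_id",
    "dose_mg",
    "interval_h",
    "time_h",
    "dlt",
)


def load_trial_csv(path) -> pd.DataFrame:
    """Read and validate a per-patient trial CSV.

    Raises ``ValueError`` naming the offending row for malformed records
    (dlt outside {0, 1}, nonpositive times or intervals, negative doses,
    duplicated patient ids).  An empty file with a header is a valid empty
    dataset.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial CSV is missing columns: {missing}")
    for i, row in df.iterrows():
        if row["dlt"] not in (0, 1):
            raise ValueError(f"row {i}: dlt must be 0 or 1, got {row['dlt']}")
        if not row["time_h"] > 0:
            raise ValueError(f"row {i}: time_h must be positive")
        if not row["interval_h"] > 0:
            raise ValueError(f"row {i}: interval_h must be positive")
        if row["dose_mg"] < 0:
            raise ValueError(f"row {i}: dose_mg must be nonnegative")
    dup = df["patient_id"].duplicated()
    if dup.any():
        raise ValueError(
            f"duplicated patient_id at rows {list(df.index[dup])}"
        )
    return df


def save_trial_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=list(REQUIRED_COLUMNS))


def to_subjects(df: pd.DataFrame, cycle_length: float = 504.0) -> list[SubjectEvent]:
    """Per-patient records as the time-to-event likelihood units."""
    return [
        SubjectEvent(
            Regimen(row.dose_mg, row.interval_h, cycle_length),
            row.time_h,
            int(row.dlt),
        )
        for row in df.itertuples()
    ]


def to_dose_tox(df: pd.DataFrame, schedule_id: str | None = None) -> DoseToxData:
    """Aggregate per-patient rows to binomial counts per dose level."""
    sub = df if schedule_id is None else df[df["schedule_id"] == schedule_id]
    return DoseToxData.from_records(
        zip(sub["dose_mg"], sub["dlt"]), schedule_id or ""
    )


def load_everolimus() -> pd.DataFrame:
    """The bundled everolimus trial dataset as a per-patient table."""
    with resources.files("titepk.data").joinpath("everolimus.csv").open() as f:
        return load_trial_csv(f)


def everolimus_subjects(
    schedules: Iterable[str] = ("weekly", "daily"),
    cycle_length: float = 504.0,
    dlt_time_h: float | None = None,
) -> list[SubjectEvent]:
    """Subject records for the chosen schedules.

    ``dlt_time_h`` overrides the recorded DLT times (all at day 15); used by
    the timing sensitivity analysis.
    """
    df = load_everolimus()
    df = df[df["schedule_id"].isin(list(schedules))].copy()
    if dlt_time_h is not None:
        df.loc[df["dlt"] == 1, "time_h"] = dlt_time_h
    return to_subjects(df, cycle_length)


def everolimus_counts(schedule: str) -> DoseToxData:
    """Binomial DLT counts of one everolimus schedule."""
    return to_dose_tox(load_everolimus(), schedule)
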