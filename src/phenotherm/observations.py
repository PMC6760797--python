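"""Reading and validating individual-level observation CSV files.

One long-format schema carries every kind of record::

    stage,temperature_c,individual_id,event,day,count

``event`` is ``molt`` (the individual completed the stage; ``day`` is the
stage duration in days), ``death`` (``day`` is the censoring time within
the stage), or ``oviposition`` (``day`` is the adult age, ``count`` the
eggs laid that day).  Malformed rows are reported with their file line
number (the header is line 1).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .fitting import StageObservations

__all__ = [
    "ObservationParseError",
    "read_observation_table",
    "read_observations",
    "stage_observations_from_table",
    "fecundity_diaries",
    "longevity_records",
    "write_observation_table",
]

VALID_EVENTS = {"molt", "death", "oviposition"}
COLUMNS = ["stage", "temperature_c", "individual_id", "event", "day", "count"]


class ObservationParseError(ValueError):
    """A malformed observation file; the message lists offending lines."""


def read_observation_table(path) -> pd.DataFrame:
    """Read and validate the long-format observation CSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, dtype={"stage": str, "event": str},
                         keep_default_na=False, na_values=[""])
    except pd.errors.EmptyDataError:
        raise ObservationParseError(f"{path}: empty input file")
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ObservationParseError(
            f"{path}: missing columns {missing} (line 1)")
    if df.empty:
        raise ObservationParseError(f"{path}: no observation rows")

    problems = []
    lines = df.index + 2  # header is line 1
    bad_event = ~df["event"].isin(VALID_EVENTS)
    for ln, ev in zip(lines[bad_event], df.loc[bad_event, "event"]):
        problems.append(f"line {ln}, column 'event': unknown event {ev!r}")
    day = pd.to_numeric(df["day"], errors="coerce")
    bad_day = day.isna() | (day <= 0)
    for ln in lines[bad_day]:
        problems.append(f"line {ln}, column 'day': non-positive or non-numeric")
    temp = pd.to_numeric(df["temperature_c"], errors="coerce")
    for ln in lines[temp.isna()]:
        problems.append(f"line {ln}, column 'temperature_c': non-numeric")
    dup = df.duplicated(["stage", "temperature_c", "individual_id", "event", "day"])
    for ln in lines[dup]:
        problems.append(f"line {ln}: duplicate record")
    if problems:
        head = "; ".join(problems[:8])
        more = f" (+{len(problems) - 8} more)" if len(problems) > 8 else ""
        raise ObservationParseError(f"{path}: {head}{more}")
    df["day"] = day
    df["temperature_c"] = temp
    return df


def stage_observations_from_table(df: pd.DataFrame, stage: str) -> StageObservations:
    """Terminal molt/death rows of one stage as a StageObservations record set."""
    sub = df[(df["stage"] == stage) & df["event"].isin(["molt", "death"])]
    records = pd.DataFrame({
        "temperature_c": sub["temperature_c"].to_numpy(dtype=float),
        "individual_id": sub["individual_id"].to_numpy(),
        "time_days": sub["day"].to_numpy(dtype=float),
        "survived": (sub["event"] == "molt").to_numpy(),
    })
    return StageObservations(stage=stage, records=records)


def read_observations(path) -> dict:
    """Parse a CSV into {stage: StageObservations} for the immature stages."""
    df = read_observation_table(path)
    stages = [s for s in df["stage"].unique()
              if not str(s).startswith("adult")]
    return {s: stage_observations_from_table(df, s) for s in stages}


def fecundity_diaries(df: pd.DataFrame) -> pd.DataFrame:
    """Oviposition rows pivoted to per-female daily diaries (long format)."""
    sub = df[df["event"] == "oviposition"].copy()
    sub["count"] = pd.to_numeric(sub["count"], errors="coerce").fillna(0).astype(int)
    return sub[["temperature_c", "individual_id", "day", "count"]].reset_index(
        drop=True)


def longevity_records(df: pd.DataFrame) -> pd.DataFrame:
    """Adult death rows as (sex, temperature_c, individual_id, lifespan_days)."""
    sub = df[df["stage"].isin(["adult_female", "adult_male"])
             & (df["event"] == "death")].copy()
    sub["sex"] = np.where(sub["stage"] == "adult_female", "female", "male")
    out = sub[["sex", "temperature_c", "individual_id", "day"]]
    return out.rename(columns={"day": "lifespan_days"}).reset_index(drop=True)


def write_observation_table(df: pd.DataFrame, path) -> None:
    """Write a validated observation table back to CSV (round-trip identity)."""
    df.to_csv(path, index=False, columns=COLUMNS)
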