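"""Readers and writers for the pipeline's CSV dialect.

All files are UTF-8, RFC-4180 quoted, with fixed documented column orders.
Timestamps are ISO-8601 at minute resolution; booleans are serialized 0/1.

Files
-----
``encounters.csv``
    one row per encounter: encounter_id, site, arrival, departure, age, sex,
    elixhauser, covid_status, weight_kg, disposition, comfort_care_time,
    true_septic
``events.csv``
    one row per clinical event: encounter_id, timestamp, channel, name,
    value, units
``sepsis_labels.csv``, ``outcomes.csv``, ``monthly_series.csv``
    one row per encounter / encounter / month respectively.
"""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd

from .records import ENCOUNTER_COLUMNS, EVENT_COLUMNS

_TIME_FMT = "%Y-%m-%dT%H:%M"

_ENC_BOOL_COLS = ("covid_status", "true_septic")
_ENC_TIME_COLS = ("arrival", "departure", "comfort_care_time")


def write_event_log(encounters_df: pd.DataFrame, events_df: pd.DataFrame, out_dir: str | Path) -> None:
    """Write ``encounters.csv`` and ``events.csv`` under *out_dir*."""
    out_dir = Path(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    enc = encounters_df.loc[:, ENCOUNTER_COLUMNS].copy()
    for col in _ENC_TIME_COLS:
        enc[col] = pd.to_datetime(enc[col]).dt.strftime(_TIME_FMT)
    for col in _ENC_BOOL_COLS:
        enc[col] = enc[col].astype(int)
    enc.to_csv(out_dir / "encounters.csv", index=False)

    ev = events_df.loc[:, EVENT_COLUMNS].copy()
    ev["timestamp"] = pd.to_datetime(ev["timestamp"]).dt.strftime(_TIME_FMT)
    ev.to_csv(out_dir / "events.csv", index=False)


def read_event_log(in_dir: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read the ``encounters.csv`` / ``events.csv`` pair back into DataFrames."""
    in_dir = Path(in_dir)
    enc = pd.read_csv(in_dir / "encounters.csv", dtype={"encounter_id": str})
    missing = set(ENCOUNTER_COLUMNS) - set(enc.columns)
    if missing:
        raise ValueError(f"encounters.csv missing columns: {sorted(missing)}")
    for col in _ENC_TIME_COLS:
        enc[col] = pd.to_datetime(enc[col], format=_TIME_FMT, errors="coerce" if col == "comfort_care_time" else "raise")
    for col in _ENC_BOOL_COLS:
        enc[col] = enc[col].astype(bool)

    ev = pd.read_csv(in_dir / "events.csv", dtype={"encounter_id": str, "units": str})
    missing = set(EVENT_COLUMNS) - set(ev.columns)
    if missing:
        raise ValueError(f"events.csv missing columns: {sorted(missing)}")
    ev["timestamp"] = pd.to_datetime(ev["timestamp"], format=_TIME_FMT)
    ev["units"] = ev["units"].fillna("")
    return enc, ev


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a derived table (labels / outcomes / monthly series) with 0/1 booleans."""
    out = df.copy()
    for col in out.columns:
        if out[col].dtype == bool:
            out[col] = out[col].astype(int)
        elif pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime(_TIME_FMT)
    os.makedirs(Path(path).parent, exist_ok=True)
    out.to_csv(path, index=False)


def read_table(path: str | Path, time_cols: tuple[str, ...] = ()) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"encounter_id": str})
    for col in time_cols:
        if col in df.columns:
            df[col] = pd.to_datetime(df[col], format=_TIME_FMT, errors="coerce")
    return df
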