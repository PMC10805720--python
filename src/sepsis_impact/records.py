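"""Core clinical-event and encounter records.

The pipeline's canonical on-disk form is a pair of CSV tables
(``encounters.csv`` one row per ED encounter, ``events.csv`` one row per
timestamped clinical event); the canonical in-memory form is a pair of
pandas DataFrames with the same columns.  :class:`EncounterRecord` is a
lightweight per-encounter view used by the phenotyping and outcome rules,
which are inherently per-patient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from typing import Optional

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Controlled vocabulary
# ---------------------------------------------------------------------------

#: Event channels.
CHANNELS = (
    "vital",
    "lab",
    "med_order",
    "med_admin",
    "culture_order",
    "fluid_admin",
    "transfer",
    "alert",
    "alert_ack",
)

#: Concept names carried on vital/lab events (units fixed by convention).
VITAL_NAMES = ("MAP", "SBP", "GCS")
LAB_NAMES = ("PaO2FiO2", "platelets", "bilirubin", "creatinine", "lactate")

#: Medication route / prophylaxis tokens carried in the ``units`` column of
#: med_order / med_admin events.  The 4-day qualifying-antibiotic rule counts
#: only ``iv-nonprophylactic`` administrations.
ROUTE_IV_NONPROPHYLACTIC = "iv-nonprophylactic"
ROUTE_IV_PROPHYLACTIC = "iv-prophylactic"
ROUTE_PO = "po"

ANTIBIOTIC_NAMES = ("ceftriaxone", "piperacillin-tazobactam", "vancomycin", "cefepime")
VASOPRESSOR_NAMES = ("norepinephrine", "epinephrine", "dopamine", "dobutamine", "vasopressin")

#: Alert acknowledgement categories (the four BPA responses).
ACK_NO_INFECTION = "no_infection"
ACK_WORKUP = "workup"
ACK_NOTIFY_MD = "notify_md"
ACK_NONE = "none"
ACK_CATEGORIES = (ACK_NO_INFECTION, ACK_WORKUP, ACK_NOTIFY_MD, ACK_NONE)

#: Unit-transfer destinations.
UNIT_ICU = "ICU"
UNIT_WARD = "ward"
UNIT_ED = "ED"

ENCOUNTER_COLUMNS = [
    "encounter_id",
    "site",
    "arrival",
    "departure",
    "age",
    "sex",
    "elixhauser",
    "covid_status",
    "weight_kg",
    "disposition",
    "comfort_care_time",
    "true_septic",
]

EVENT_COLUMNS = ["encounter_id", "timestamp", "channel", "name", "value", "units"]


@dataclass
class ClinicalEvent:
    """A single timestamped clinical observation or action."""

    timestamp: datetime
    channel: str
    name: str
    value: float | str
    units: str = ""

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown event channel: {self.channel!r}")


@dataclass
class EncounterRecord:
    """One ED encounter: demographics, disposition and its ordered event stream."""

    encounter_id: str
    site: str
    arrival: datetime
    departure: datetime
    age: float
    sex: str
    elixhauser: int
    covid_status: bool
    weight_kg: Optional[float]
    disposition: str  # "discharged" | "died"
    comfort_care_time: Optional[datetime] = None
    true_septic: bool = False
    events: list[ClinicalEvent] = field(default_factory=list)

    def sorted_events(self) -> list[ClinicalEvent]:
        return sorted(self.events, key=lambda e: (e.timestamp, e.channel, e.name))

    @property
    def death_time(self) -> Optional[datetime]:
        return self.departure if self.disposition == "died" else None


def encounters_to_frame(encounters: list[EncounterRecord]) -> pd.DataFrame:
    """Flatten encounter metadata (without events) into a DataFrame."""
    rows = []
    for enc in encounters:
        rows.append(
            {
                "encounter_id": enc.encounter_id,
                "site": enc.site,
                "arrival": enc.arrival,
                "departure": enc.departure,
                "age": enc.age,
                "sex": enc.sex,
                "elixhauser": enc.elixhauser,
                "covid_status": enc.covid_status,
                "weight_kg": enc.weight_kg,
                "disposition": enc.disposition,
                "comfort_care_time": enc.comfort_care_time,
                "true_septic": enc.true_septic,
            }
        )
    df = pd.DataFrame(rows, columns=ENCOUNTER_COLUMNS)
    for col in ("arrival", "departure", "comfort_care_time"):
        df[col] = pd.to_datetime(df[col])
    return df


def events_to_frame(encounters: list[EncounterRecord]) -> pd.DataFrame:
    """Flatten all event streams into a single long DataFrame, time-sorted per encounter."""
    ids, ts, ch, nm, val, un = [], [], [], [], [], []
    for enc in encounters:
        for ev in enc.sorted_events():
            ids.append(enc.encounter_id)
            ts.append(ev.timestamp)
            ch.append(ev.channel)
            nm.append(ev.name)
            val.append(ev.value)
            un.append(ev.units)
    df = pd.DataFrame(
        {
            "encounter_id": ids,
            "timestamp": pd.to_datetime(ts),
            "channel": ch,
            "name": nm,
            "value": val,
            "units": un,
        },
        columns=EVENT_COLUMNS,
    )
    return df


def frames_to_encounters(
    encounters_df: pd.DataFrame, events_df: pd.DataFrame
) -> list[EncounterRecord]:
    """Reassemble EncounterRecord objects from the two flat tables.

    Events are re-sorted by timestamp, so adjudication is invariant to the
    row order of ``events.csv``.
    """
    bad = set(events_df["channel"].unique()) - set(CHANNELS)
    if bad:
        raise ValueError(f"unknown event channels in input: {sorted(bad)}")
    grouped: dict[str, list[ClinicalEvent]] = {}
    ev = events_df.sort_values("timestamp", kind="mergesort")
    for enc_id, ts, ch, nm, val, un in zip(
        ev["encounter_id"], ev["timestamp"], ev["channel"], ev["name"], ev["value"], ev["units"]
    ):
        grouped.setdefault(enc_id, []).append(
            ClinicalEvent(ts.to_pydatetime(), ch, nm, val, "" if pd.isna(un) else un)
        )
    out = []
    for row in encounters_df.itertuples(index=False):
        cc = None if pd.isna(row.comfort_care_time) else row.comfort_care_time.to_pydatetime()
        out.append(
            EncounterRecord(
                encounter_id=row.encounter_id,
                site=row.site,
                arrival=row.arrival.to_pydatetime(),
                departure=row.departure.to_pydatetime(),
                age=float(row.age),
                sex=row.sex,
                elixhauser=int(row.elixhauser),
                covid_status=bool(row.covid_status),
                weight_kg=None if pd.isna(row.weight_kg) else float(row.weight_kg),
                disposition=row.disposition,
                comfort_care_time=cc,
                true_septic=bool(row.true_septic),
                events=grouped.get(row.encounter_id, []),
            )
        )
    return out


def _numeric_value(value) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        return np.nan
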