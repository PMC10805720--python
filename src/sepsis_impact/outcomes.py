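"""Primary and secondary outcomes for included septic encounters.

Outcomes follow the study's definitions: in-hospital mortality; 72-h change
in SOFA after sepsis onset (worst value within 72 h minus the value at
onset); ICU transfer; ICU-free days (30 minus ICU days, 0 for in-ICU death
or >= 30 ICU days); per-element and composite sepsis-bundle compliance; and
time from ED triage to first antibiotic administration.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta
from math import ceil
from typing import Optional

import pandas as pd

from .phenotyping import sofa_at, sofa_measurement_times, _is_abx, _is_vasopressor
from .records import EncounterRecord, UNIT_ICU

HOUR = timedelta(hours=1)

BUNDLE_ELEMENTS = (
    "blood_culture_before_abx",
    "abx_timely",
    "initial_lactate",
    "repeat_lactate",
    "vasoactives_timely",
    "fluids_timely",
)

# Windows (hours relative to onset / shock presentation)
ABX_WINDOW = (-24.0, 3.0)
LACTATE_WINDOW = (-6.0, 3.0)
REPEAT_LACTATE_HOURS = 6.0
VASOACTIVE_HOURS = 6.0
FLUID_HOURS = 3.0
FLUID_ML_PER_KG = 30.0
LACTATE_ELEVATED = 2.0

# Shock / hypotension presentation thresholds (configurable convention)
SHOCK_MAP = 65.0
SHOCK_SBP = 90.0
SHOCK_LACTATE = 4.0


@dataclass
class BundleElement:
    applicable: bool
    met: Optional[bool]  # None = indeterminate (e.g. missing weight)


@dataclass
class OutcomeRecord:
    encounter_id: str
    died_in_hospital: bool
    delta_sofa_72h: int
    icu_transfer: bool
    icu_free_days: int
    bundle: dict[str, BundleElement]
    composite_compliant: bool
    time_to_abx_hours: Optional[float]
    ack_category: str  # no_infection | workup | notify_md | none | no_alert


# ---------------------------------------------------------------------------
# ICU-free days
# ---------------------------------------------------------------------------

def icu_free_days(icu_intervals: list[tuple[datetime, datetime]], died_in_icu: bool) -> int:
    """30 minus total ICU days (hours rounded up), 0 for in-ICU death or >= 30 days.

    A surviving patient with 4 ICU days scores 26; no ICU time scores 30.
    """
    intervals = sorted(icu_intervals)
    for (s1, e1), (s2, _) in zip(intervals, intervals[1:]):
        if s2 < e1:
            raise ValueError("overlapping ICU intervals")
    for s, e in intervals:
        if e < s:
            raise ValueError("ICU interval ends before it starts")
    if died_in_icu:
        return 0
    total_hours = sum((e - s).total_seconds() / 3600.0 for s, e in intervals)
    days = ceil(total_hours / 24.0 - 1e-9) if total_hours > 0 else 0
    if days >= 30:
        return 0
    return max(0, min(30, 30 - days))


def icu_intervals_from_events(events, departure: datetime) -> list[tuple[datetime, datetime]]:
    """ICU stay intervals from unit-transfer events; an open stay closes at departure."""
    transfers = sorted(
        (ev.timestamp, ev.name) for ev in events if ev.channel == "transfer"
    )
    intervals = []
    icu_start: Optional[datetime] = None
    for t, unit in transfers:
        if unit == UNIT_ICU and icu_start is None:
            icu_start = t
        elif unit != UNIT_ICU and icu_start is not None:
            intervals.append((icu_start, t))
            icu_start = None
    if icu_start is not None:
        intervals.append((icu_start, departure))
    return intervals


# ---------------------------------------------------------------------------
# 72-h SOFA change
# ---------------------------------------------------------------------------

def delta_sofa_72h(events, onset: datetime) -> int:
    """Worst SOFA total in ``(onset, onset + 72 h]`` minus the total at onset.

    Patients dying within 72 h contribute their observed maximum.
    """
    at_onset = sofa_at(events, onset).total
    hi = onset + timedelta(hours=72)
    times = [t for t in sofa_measurement_times(events, onset, hi) if t > onset]
    worst = max((sofa_at(events, t).total for t in times), default=at_onset)
    return max(worst, at_onset) - at_onset


# ---------------------------------------------------------------------------
# Bundle compliance
# ---------------------------------------------------------------------------

def _first_time(events, predicate) -> Optional[datetime]:
    times = [ev.timestamp for ev in events if predicate(ev)]
    return min(times) if times else None


def shock_presentation(events, onset: datetime) -> tuple[Optional[datetime], bool, bool]:
    """(presentation time, shock, hypotension) after onset.

    Presentation is the first time at or after onset with MAP < 65 mmHg,
    SBP < 90 mmHg, or lactate >= 4 mmol/L.  Shock requires the lactate
    criterion or hypotension; the two flags drive element applicability.
    """
    hypo_t = None
    lact_t = None
    for ev in sorted(events, key=lambda e: e.timestamp):
        if ev.timestamp < onset:
            continue
        if ev.channel == "vital" and ev.name == "MAP" and float(ev.value) < SHOCK_MAP and hypo_t is None:
            hypo_t = ev.timestamp
        if ev.channel == "vital" and ev.name == "SBP" and float(ev.value) < SHOCK_SBP and hypo_t is None:
            hypo_t = ev.timestamp
        if ev.channel == "lab" and ev.name == "lactate" and float(ev.value) >= SHOCK_LACTATE and lact_t is None:
            lact_t = ev.timestamp
    times = [t for t in (hypo_t, lact_t) if t is not None]
    if not times:
        return None, False, False
    return min(times), lact_t is not None or hypo_t is not None, hypo_t is not None


def bundle_compliance(
    events, onset: datetime, weight_kg: Optional[float]
) -> tuple[dict[str, BundleElement], bool]:
    """Evaluate each bundle element on its own time window; composite = all applicable met.

    An applicable fluid element with missing weight is indeterminate and is
    excluded from the composite denominator.
    """
    events = sorted(events, key=lambda e: e.timestamp)
    first_culture = _first_time(events, lambda e: e.channel == "culture_order")
    first_abx_admin = _first_time(events, lambda e: e.channel == "med_admin" and _is_abx(e.name))

    out: dict[str, BundleElement] = {}

    # blood cultures drawn before the first antibiotic administration
    if first_abx_admin is not None:
        met = first_culture is not None and first_culture <= first_abx_admin
        out["blood_culture_before_abx"] = BundleElement(True, met)
    else:
        out["blood_culture_before_abx"] = BundleElement(False, None)

    # antibiotics within 24 h before to 3 h after onset
    lo = onset + timedelta(hours=ABX_WINDOW[0])
    hi = onset + timedelta(hours=ABX_WINDOW[1])
    met = any(
        lo <= e.timestamp <= hi for e in events if e.channel == "med_admin" and _is_abx(e.name)
    )
    out["abx_timely"] = BundleElement(True, met)

    # initial lactate within 6 h before to 3 h after onset
    lo = onset + timedelta(hours=LACTATE_WINDOW[0])
    hi = onset + timedelta(hours=LACTATE_WINDOW[1])
    lactates = [(e.timestamp, float(e.value)) for e in events if e.channel == "lab" and e.name == "lactate"]
    out["initial_lactate"] = BundleElement(True, any(lo <= t <= hi for t, _ in lactates))

    # repeat lactate within 6 h of the first, applicable only if it was elevated
    if lactates:
        t0, v0 = min(lactates)
        if v0 > LACTATE_ELEVATED:
            met = any(t0 < t <= t0 + timedelta(hours=REPEAT_LACTATE_HOURS) for t, _ in lactates)
            out["repeat_lactate"] = BundleElement(True, met)
        else:
            out["repeat_lactate"] = BundleElement(False, None)
    else:
        out["repeat_lactate"] = BundleElement(False, None)

    present_t, shock, hypotension = shock_presentation(events, onset)

    # vasoactives within 6 h of septic-shock presentation
    if shock and present_t is not None:
        met = any(
            present_t <= e.timestamp <= present_t + timedelta(hours=VASOACTIVE_HOURS)
            for e in events
            if e.channel == "med_admin" and _is_vasopressor(e.name)
        )
        out["vasoactives_timely"] = BundleElement(True, met)
    else:
        out["vasoactives_timely"] = BundleElement(False, None)

    # 30 mL/kg crystalloid within 3 h of shock / hypotension presentation
    if (shock or hypotension) and present_t is not None:
        if weight_kg is None:
            out["fluids_timely"] = BundleElement(True, None)  # indeterminate
        else:
            vol = sum(
                float(e.value)
                for e in events
                if e.channel == "fluid_admin"
                and present_t <= e.timestamp <= present_t + timedelta(hours=FLUID_HOURS)
            )
            out["fluids_timely"] = BundleElement(True, vol >= FLUID_ML_PER_KG * weight_kg)
    else:
        out["fluids_timely"] = BundleElement(False, None)

    composite = all(
        el.met for el in out.values() if el.applicable and el.met is not None
    )
    return out, composite


# ---------------------------------------------------------------------------
# Time to antibiotics / acknowledgement
# ---------------------------------------------------------------------------

def time_to_antibiotics(events, arrival: datetime) -> Optional[float]:
    """Hours from ED triage to the first antibiotic administration; None if never given."""
    first = _first_time(events, lambda e: e.channel == "med_admin" and _is_abx(e.name))
    if first is None:
        return None
    if first < arrival:
        raise ValueError("antibiotic administration precedes arrival")
    return (first - arrival).total_seconds() / 3600.0


def ack_category(events) -> str:
    """Acknowledgement of the first alert; 'no_alert' when no alert fired."""
    alerts = sorted(e.timestamp for e in events if e.channel == "alert")
    if not alerts:
        return "no_alert"
    acks = sorted((e.timestamp, e.name) for e in events if e.channel == "alert_ack")
    for t, name in acks:
        if t >= alerts[0]:
            return name
    return "none"


# ---------------------------------------------------------------------------
# Batch derivation
# ---------------------------------------------------------------------------

def derive_outcome(enc: EncounterRecord, onset: datetime) -> OutcomeRecord:
    events = enc.sorted_events()
    intervals = icu_intervals_from_events(events, enc.departure)
    died = enc.disposition == "died"
    died_in_icu = died and any(s <= enc.departure <= e for s, e in intervals)
    bundle, composite = bundle_compliance(events, onset, enc.weight_kg)
    return OutcomeRecord(
        encounter_id=enc.encounter_id,
        died_in_hospital=died,
        delta_sofa_72h=delta_sofa_72h(events, onset),
        icu_transfer=bool(intervals),
        icu_free_days=icu_free_days(intervals, died_in_icu),
        bundle=bundle,
        composite_compliant=composite,
        time_to_abx_hours=time_to_antibiotics(events, enc.arrival),
        ack_category=ack_category(events),
    )


def derive_outcomes(encounters: list[EncounterRecord], labels: pd.DataFrame) -> pd.DataFrame:
    """One row per *included* septic encounter (``outcomes.csv`` shape)."""
    by_id = {e.encounter_id: e for e in encounters}
    rows = []
    for row in labels.itertuples(index=False):
        if not row.included:
            continue
        enc = by_id[row.encounter_id]
        rec = derive_outcome(enc, row.onset_time.to_pydatetime())
        flat = {
            "encounter_id": rec.encounter_id,
            "died_in_hospital": rec.died_in_hospital,
            "delta_sofa_72h": rec.delta_sofa_72h,
            "icu_transfer": rec.icu_transfer,
            "icu_free_days": rec.icu_free_days,
            "composite_compliant": rec.composite_compliant,
            "time_to_abx_hours": rec.time_to_abx_hours,
            "ack_category": rec.ack_category,
        }
        for name, el in rec.bundle.items():
            flat[f"{name}_applicable"] = el.applicable
            flat[f"{name}_met"] = "" if el.met is None else int(el.met)
        rows.append(flat)
    return pd.DataFrame(rows)
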