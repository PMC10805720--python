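"""Sepsis-3 electronic phenotype.

Suspicion of infection is the co-occurrence of a blood-culture order and a
qualifying course of non-prophylactic intravenous antibiotics: if the
culture is ordered first the antibiotic order must follow within 72 h; if
the antibiotic order comes first the culture must follow within 24 h.  The
qualifying course requires at least 4 consecutive calendar days each with
an IV non-prophylactic administration, with truncation by death or
discharge before day 4 still qualifying.  Organ dysfunction is an increase
of >= 2 SOFA points over baseline in the window 48 h before to 24 h after
suspicion; sepsis onset is the suspicion time.  Included encounters are
adults whose onset falls within 12 h of ED arrival and who were not
transitioned to comfort care before onset.

All window boundaries are closed at minute resolution ("within 72 h" means
<= 72:00 exactly).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Optional

import pandas as pd

from .records import ANTIBIOTIC_NAMES, EncounterRecord, ROUTE_IV_NONPROPHYLACTIC, VASOPRESSOR_NAMES

HOUR = timedelta(hours=1)

CULTURE_TO_ABX = timedelta(hours=72)
ABX_TO_CULTURE = timedelta(hours=24)
SOFA_WINDOW_BEFORE = timedelta(hours=48)
SOFA_WINDOW_AFTER = timedelta(hours=24)
ONSET_LIMIT = timedelta(hours=12)
DEFAULT_LOOKBACK = timedelta(hours=24)
MIN_QUALIFYING_DAYS = 4


@dataclass
class SuspicionEpisode:
    culture_time: datetime
    abx_start: datetime
    qualifying_abx_days: int
    suspicion_time: datetime
    qualified: bool


@dataclass
class SofaAssessment:
    time: datetime
    respiration: int
    coagulation: int
    liver: int
    cardiovascular: int
    cns: int
    renal: int

    @property
    def total(self) -> int:
        return (
            self.respiration
            + self.coagulation
            + self.liver
            + self.cardiovascular
            + self.cns
            + self.renal
        )


@dataclass
class SepsisLabel:
    encounter_id: str
    suspicion: Optional[SuspicionEpisode]
    baseline_sofa: int
    delta_sofa_at_adjudication: int
    onset_time: Optional[datetime]
    included: bool
    exclusion_reason: Optional[str]  # no_sepsis | comfort_care_before_onset | onset_after_12h | age_under_18


# ---------------------------------------------------------------------------
# SOFA sub-scores (standard published thresholds)
# ---------------------------------------------------------------------------

def respiration_score(pao2fio2: Optional[float]) -> int:
    if pao2fio2 is None:
        return 0
    if pao2fio2 >= 400:
        return 0
    if pao2fio2 >= 300:
        return 1
    if pao2fio2 >= 200:
        return 2
    if pao2fio2 >= 100:
        return 3
    return 4


def coagulation_score(platelets: Optional[float]) -> int:
    if platelets is None:
        return 0
    if platelets >= 150:
        return 0
    if platelets >= 100:
        return 1
    if platelets >= 50:
        return 2
    if platelets >= 20:
        return 3
    return 4


def liver_score(bilirubin: Optional[float]) -> int:
    if bilirubin is None:
        return 0
    if bilirubin < 1.2:
        return 0
    if bilirubin < 2.0:
        return 1
    if bilirubin < 6.0:
        return 2
    if bilirubin < 12.0:
        return 3
    return 4


def cardiovascular_score(
    map_mmHg: Optional[float],
    dopamine: float = 0.0,
    dobutamine: float = 0.0,
    norepinephrine: float = 0.0,
    epinephrine: float = 0.0,
    vasopressin: float = 0.0,
) -> int:
    if dopamine > 15 or norepinephrine > 0.1 or epinephrine > 0.1:
        return 4
    if dopamine > 5 or (0 < norepinephrine <= 0.1) or (0 < epinephrine <= 0.1) or vasopressin > 0:
        return 3
    if 0 < dopamine <= 5 or dobutamine > 0:
        return 2
    if map_mmHg is not None and map_mmHg < 70:
        return 1
    return 0


def cns_score(gcs: Optional[float]) -> int:
    if gcs is None or gcs >= 15:
        return 0
    if gcs >= 13:
        return 1
    if gcs >= 10:
        return 2
    if gcs >= 6:
        return 3
    return 4


def renal_score(creatinine: Optional[float]) -> int:
    if creatinine is None:
        return 0
    if creatinine < 1.2:
        return 0
    if creatinine < 2.0:
        return 1
    if creatinine < 3.5:
        return 2
    if creatinine < 5.0:
        return 3
    return 4


def _is_abx(name: str) -> bool:
    return name in ANTIBIOTIC_NAMES


def _is_vasopressor(name: str) -> bool:
    return name in VASOPRESSOR_NAMES


def sofa_at(events, t: datetime, lookback: timedelta = DEFAULT_LOOKBACK) -> SofaAssessment:
    """SOFA total at time *t* from the worst measurement in ``(t - lookback, t]``.

    A channel with no measurement in the window scores 0 (missing-as-normal).
    The cardiovascular sub-score combines the worst MAP with the vasopressor
    administration state over the same window.
    """
    lo = t - lookback
    worst = {"PaO2FiO2": None, "platelets": None, "bilirubin": None, "creatinine": None,
             "MAP": None, "GCS": None}
    doses = {name: 0.0 for name in VASOPRESSOR_NAMES}
    for ev in events:
        if not (lo < ev.timestamp <= t):
            continue
        if ev.channel in ("lab", "vital") and ev.name in worst:
            v = float(ev.value)
            cur = worst[ev.name]
            # "worst" is the minimum for all these channels except bilirubin/creatinine
            if ev.name in ("bilirubin", "creatinine"):
                worst[ev.name] = v if cur is None else max(cur, v)
            else:
                worst[ev.name] = v if cur is None else min(cur, v)
        elif ev.channel == "med_admin" and _is_vasopressor(ev.name):
            doses[ev.name] = max(doses[ev.name], float(ev.value))
    return SofaAssessment(
        time=t,
        respiration=respiration_score(worst["PaO2FiO2"]),
        coagulation=coagulation_score(worst["platelets"]),
        liver=liver_score(worst["bilirubin"]),
        cardiovascular=cardiovascular_score(
            worst["MAP"],
            dopamine=doses["dopamine"],
            dobutamine=doses["dobutamine"],
            norepinephrine=doses["norepinephrine"],
            epinephrine=doses["epinephrine"],
            vasopressin=doses["vasopressin"],
        ),
        cns=cns_score(worst["GCS"]),
        renal=renal_score(worst["creatinine"]),
    )


_SOFA_CHANNELS = {"lab", "vital"}


def sofa_measurement_times(events, lo: datetime, hi: datetime) -> list[datetime]:
    """Times in [lo, hi] at which a SOFA-relevant measurement lands."""
    times = set()
    for ev in events:
        if lo <= ev.timestamp <= hi and (
            (ev.channel in _SOFA_CHANNELS and ev.name in ("PaO2FiO2", "platelets", "bilirubin",
                                                          "creatinine", "MAP", "GCS"))
            or (ev.channel == "med_admin" and _is_vasopressor(ev.name))
        ):
            times.add(ev.timestamp)
    return sorted(times)


# ---------------------------------------------------------------------------
# Suspicion of infection
# ---------------------------------------------------------------------------

def qualifying_antibiotic_days(events, departure: datetime) -> int:
    """Consecutive calendar days with >= 1 non-prophylactic IV antibiotic administration.

    The streak starts on the day of the first qualifying administration.
    """
    days = sorted(
        {
            ev.timestamp.date()
            for ev in events
            if ev.channel == "med_admin" and _is_abx(ev.name) and ev.units == ROUTE_IV_NONPROPHYLACTIC
        }
    )
    if not days:
        return 0
    count = 1
    for prev, cur in zip(days, days[1:]):
        if (cur - prev).days == 1:
            count += 1
        else:
            break
    return count


def antibiotic_course_qualifies(events, departure: datetime) -> bool:
    """>= 4 consecutive qualifying days, or a course truncated by the end of the encounter.

    A patient dosed daily until death or discharge before day 4 still
    qualifies (surveillance-style death/discharge exception).
    """
    days = sorted(
        {
            ev.timestamp.date()
            for ev in events
            if ev.channel == "med_admin" and _is_abx(ev.name) and ev.units == ROUTE_IV_NONPROPHYLACTIC
        }
    )
    if not days:
        return False
    k = qualifying_antibiotic_days(events, departure)
    if k >= MIN_QUALIFYING_DAYS:
        return True
    return days[0] + timedelta(days=k) >= departure.date()


def detect_suspicion(events, departure: Optional[datetime] = None) -> Optional[SuspicionEpisode]:
    """Earliest qualifying (culture order, antibiotic order) pair.

    Suspicion time is the earlier member of the qualifying pair.  The
    4-day antibiotic-course requirement (with truncation exception when
    *departure* is given) gates qualification.
    """
    cultures = sorted(ev.timestamp for ev in events if ev.channel == "culture_order")
    abx_orders = sorted(
        ev.timestamp
        for ev in events
        if ev.channel == "med_order" and _is_abx(ev.name) and ev.units == ROUTE_IV_NONPROPHYLACTIC
    )
    if not cultures or not abx_orders:
        return None
    if departure is None:
        departure = max(ev.timestamp for ev in events)
    course_ok = antibiotic_course_qualifies(events, departure)
    n_days = qualifying_antibiotic_days(events, departure)

    best: Optional[tuple[datetime, datetime]] = None  # (culture, abx)
    for c in cultures:
        for a in abx_orders:
            if (c <= a <= c + CULTURE_TO_ABX) or (a <= c <= a + ABX_TO_CULTURE):
                if best is None or min(c, a) < min(best):
                    best = (c, a)
    if best is None:
        return None
    c, a = best
    return SuspicionEpisode(
        culture_time=c,
        abx_start=a,
        qualifying_abx_days=n_days,
        suspicion_time=min(c, a),
        qualified=course_ok,
    )


# ---------------------------------------------------------------------------
# Adjudication
# ---------------------------------------------------------------------------

def adjudicate(enc: EncounterRecord, lookback: timedelta = DEFAULT_LOOKBACK) -> SepsisLabel:
    """Apply the full Sepsis-3 inclusion rule to one encounter."""
    events = enc.sorted_events()
    episode = detect_suspicion(events, enc.departure)

    def _label(included, reason, baseline=0, delta=0, onset=None):
        return SepsisLabel(
            encounter_id=enc.encounter_id,
            suspicion=episode,
            baseline_sofa=baseline,
            delta_sofa_at_adjudication=delta,
            onset_time=onset,
            included=included,
            exclusion_reason=reason,
        )

    if episode is None or not episode.qualified:
        return _label(False, "no_sepsis")

    susp = episode.suspicion_time
    lo, hi = susp - SOFA_WINDOW_BEFORE, susp + SOFA_WINDOW_AFTER

    # Baseline: minimum SOFA over [suspicion - 48 h, suspicion]; 0 if no data.
    base_times = sofa_measurement_times(events, lo, susp)
    baseline = min((sofa_at(events, t, lookback).total for t in base_times), default=0)
    # Organ dysfunction: max SOFA over [suspicion - 48 h, suspicion + 24 h].
    window_times = sofa_measurement_times(events, lo, hi)
    max_sofa = max((sofa_at(events, t, lookback).total for t in window_times), default=0)
    delta = max_sofa - baseline

    if delta < 2:
        return _label(False, "no_sepsis", baseline, delta)
    if susp - enc.arrival > ONSET_LIMIT:
        return _label(False, "onset_after_12h", baseline, delta, None)
    if enc.age < 18:
        return _label(False, "age_under_18", baseline, delta, None)
    if enc.comfort_care_time is not None and enc.comfort_care_time <= susp:
        return _label(False, "comfort_care_before_onset", baseline, delta, None)
    return _label(True, None, baseline, delta, susp)


def adjudicate_cohort(encounters: list[EncounterRecord], lookback: timedelta = DEFAULT_LOOKBACK) -> pd.DataFrame:
    """Adjudicate every encounter; one row per encounter (``sepsis_labels.csv`` shape)."""
    rows = []
    for enc in encounters:
        lab = adjudicate(enc, lookback)
        rows.append(
            {
                "encounter_id": lab.encounter_id,
                "included": lab.included,
                "exclusion_reason": lab.exclusion_reason or "",
                "suspicion_time": lab.suspicion.suspicion_time if lab.suspicion else pd.NaT,
                "culture_time": lab.suspicion.culture_time if lab.suspicion else pd.NaT,
                "abx_order_time": lab.suspicion.abx_start if lab.suspicion else pd.NaT,
                "qualifying_abx_days": lab.suspicion.qualifying_abx_days if lab.suspicion else 0,
                "baseline_sofa": lab.baseline_sofa,
                "delta_sofa_at_adjudication": lab.delta_sofa_at_adjudication,
                "onset_time": lab.onset_time if lab.onset_time else pd.NaT,
            }
        )
    df = pd.DataFrame(rows)
    for col in ("suspicion_time", "culture_time", "abx_order_time", "onset_time"):
        df[col] = pd.to_datetime(df[col])
    return df
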