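"""Monthly aggregation of encounter-level outcomes and the input-drift check.

Outcomes are analyzed at monthly resolution to damp encounter-level noise.
Each month contributes one point: the mean outcome over septic encounters
arriving that month, a covariate vector (ED volume over all comers, cohort
demographics, COVID positivity, site mix, calendar-quarter dummies), a
pre/post label relative to the go-live month, and the septic count.

The go-live month itself is assigned wholly to the post period.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd

logger = logging.getLogger("sepsis_impact")

#: outcome name -> outcomes.csv column; rates are means of 0/1 columns.
OUTCOME_REGISTRY = {
    "mortality": "died_in_hospital",
    "delta_sofa_72h": "delta_sofa_72h",
    "icu_transfer": "icu_transfer",
    "icu_free_days": "icu_free_days",
    "composite_compliance": "composite_compliant",
    "blood_culture_before_abx": "blood_culture_before_abx_met",
    "abx_timely": "abx_timely_met",
    "initial_lactate": "initial_lactate_met",
    "repeat_lactate": "repeat_lactate_met",
    "vasoactives_timely": "vasoactives_timely_met",
    "fluids_timely": "fluids_timely_met",
}

COVARIATE_COLUMNS = [
    "ed_volume",
    "pct_male",
    "mean_age",
    "mean_baseline_sofa",
    "mean_elixhauser",
    "covid_rate",
    "site_mix",
    "season_q2",
    "season_q3",
    "season_q4",
]


@dataclass
class DriftReport:
    feature: str
    observed_median: float
    lower_limit: float
    upper_limit: float
    in_control: bool


def aggregate_monthly(
    outcomes: pd.DataFrame,
    encounters: pd.DataFrame,
    labels: pd.DataFrame,
    outcome_name: str,
    go_live: date,
) -> pd.DataFrame:
    """Build the monthly series for one outcome (``monthly_series.csv`` shape).

    ``ed_volume`` counts all encounters (septic or not) arriving each month;
    every other covariate is averaged over that month's included septic
    encounters.  Months with zero septic encounters are dropped with a
    warning.  Zero-variance covariate columns are logged (the regression
    cannot identify their coefficients).
    """
    if outcome_name not in OUTCOME_REGISTRY:
        raise KeyError(f"unknown outcome {outcome_name!r}; choose from {sorted(OUTCOME_REGISTRY)}")
    col = OUTCOME_REGISTRY[outcome_name]

    enc = encounters.copy()
    enc["month"] = pd.to_datetime(enc["arrival"]).dt.to_period("M")
    volume = enc.groupby("month").size()

    septic = outcomes.merge(
        labels[["encounter_id", "baseline_sofa"]], on="encounter_id", how="left"
    ).merge(
        enc[["encounter_id", "month", "arrival", "age", "sex", "elixhauser", "covid_status", "site"]],
        on="encounter_id",
        how="left",
    )
    if septic[col].dtype == object:
        septic[col] = pd.to_numeric(septic[col], errors="coerce")

    sites = sorted(enc["site"].unique())
    ref_site = sites[0]
    go_live_month = pd.Period(freq="M", year=go_live.year, month=go_live.month)

    rows = []
    for month in sorted(volume.index):
        grp = septic[septic["month"] == month]
        n = len(grp)
        if n == 0:
            logger.warning("month %s has zero septic encounters; dropped", month)
            continue
        y = grp[col].mean(skipna=True)
        if not np.isfinite(y):
            logger.warning("month %s has no evaluable %s; dropped", month, outcome_name)
            continue
        quarter = (month.month - 1) // 3 + 1
        rows.append(
            {
                "month": str(month),
                "y": float(y),
                "ed_volume": int(volume.loc[month]),
                "pct_male": float((grp["sex"] == "male").mean()),
                "mean_age": float(grp["age"].mean()),
                "mean_baseline_sofa": float(grp["baseline_sofa"].mean()),
                "mean_elixhauser": float(grp["elixhauser"].mean()),
                "covid_rate": float(grp["covid_status"].astype(bool).mean()),
                "site_mix": float((grp["site"] == ref_site).mean()),
                "season_q2": int(quarter == 2),
                "season_q3": int(quarter == 3),
                "season_q4": int(quarter == 4),
                "period": "post" if month >= go_live_month else "pre",
                "n": n,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no months with septic encounters")
    for c in COVARIATE_COLUMNS:
        if df[c].nunique() <= 1:
            logger.warning("covariate %s has zero variance across months", c)
    return df


def drift_check(
    feature_medians: dict[str, float], control_limits: dict[str, tuple[float, float]]
) -> list[DriftReport]:
    """Compare observed feature medians with their process-control limits.

    Limits are closed intervals: a median exactly at a limit is in control.
    """
    reports = []
    for feature, median in feature_medians.items():
        lo, hi = control_limits[feature]
        if not (np.isfinite(lo) and np.isfinite(hi)) or lo > hi:
            raise ValueError(f"invalid control limits for {feature}: ({lo}, {hi})")
        reports.append(
            DriftReport(
                feature=feature,
                observed_median=float(median),
                lower_limit=float(lo),
                upper_limit=float(hi),
                in_control=bool(lo <= median <= hi),
            )
        )
    return reports
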