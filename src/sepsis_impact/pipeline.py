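"""End-to-end pipeline: simulate -> phenotype -> outcomes -> aggregate -> impact -> associate.

Every stage is a pure function of (inputs, config, seed); stage outputs are
written as CSV/JSON under the run directory, and a summary report collects
per-outcome counterfactual estimates in the shape of an impact table
(pre-period value, expected post value with interval, actual post value,
significance by interval exclusion).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import causal_impact, io, outcomes as outcomes_mod, phenotyping, synthetic_ehr, timeseries
from .association_stats import fit_time_to_abx_model
from .causal_impact import BstsConfig
from .synthetic_ehr import SimConfig

logger = logging.getLogger("sepsis_impact")

DEFAULT_OUTCOMES = [
    "mortality",
    "composite_compliance",
    "blood_culture_before_abx",
    "abx_timely",
    "initial_lactate",
    "repeat_lactate",
    "vasoactives_timely",
    "fluids_timely",
    "delta_sofa_72h",
    "icu_transfer",
    "icu_free_days",
]


class PipelineError(RuntimeError):
    """A stage failure carrying the stage name and a machine-readable code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class RunConfig:
    out_dir: str = "run_output"
    sim: SimConfig = field(default_factory=SimConfig)
    bsts: BstsConfig = field(default_factory=BstsConfig)
    outcome_names: list[str] = field(default_factory=lambda: list(DEFAULT_OUTCOMES))
    render_plots: bool = True
    seed: int = 0

    def validate(self) -> None:
        self.sim.validate()
        self.bsts.validate()
        bad = set(self.outcome_names) - set(timeseries.OUTCOME_REGISTRY)
        if bad:
            raise ValueError(f"unknown outcome names: {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", {})
        for key in ("start_date", "end_date", "go_live"):
            if key in sim_raw and isinstance(sim_raw[key], str):
                sim_raw[key] = date.fromisoformat(sim_raw[key])
        if "ack_distribution" in sim_raw:
            sim_raw["ack_distribution"] = tuple(sim_raw["ack_distribution"])
        bsts_raw = raw.pop("bsts", {})
        cfg = cls(sim=SimConfig(**sim_raw), bsts=BstsConfig(**bsts_raw), **raw)
        if "seed" not in sim_raw:
            cfg.sim.seed = cfg.seed
        if "seed" not in bsts_raw:
            cfg.bsts.seed = cfg.seed
        cfg.validate()
        return cfg


def _stage(name: str, code: str = "stage_failure"):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.time()
            try:
                result = fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raise with stage context
                raise PipelineError(name, code, str(exc)) from exc
            logger.info("stage %s finished in %.1fs", name, time.time() - t0)
            return result
        return wrapped
    return deco


@_stage("simulate")
def stage_simulate(config: RunConfig, out_dir: Path):
    from .records import encounters_to_frame, events_to_frame

    encounters = synthetic_ehr.simulate(config.sim)
    enc_df = encounters_to_frame(encounters)
    ev_df = events_to_frame(encounters)
    io.write_event_log(enc_df, ev_df, out_dir)
    logger.info("simulate: %d encounters, %d events", len(enc_df), len(ev_df))
    return encounters, enc_df, ev_df


@_stage("phenotype")
def stage_phenotype(encounters, out_dir: Path) -> pd.DataFrame:
    labels = phenotyping.adjudicate_cohort(encounters)
    io.write_table(labels, out_dir / "sepsis_labels.csv")
    logger.info("phenotype: %d encounters, %d included", len(labels), int(labels["included"].sum()))
    return labels


@_stage("outcomes")
def stage_outcomes(encounters, labels: pd.DataFrame, out_dir: Path) -> pd.DataFrame:
    out = outcomes_mod.derive_outcomes(encounters, labels)
    io.write_table(out, out_dir / "outcomes.csv")
    logger.info("outcomes: %d included septic encounters", len(out))
    return out


@_stage("impact")
def stage_impact(
    config: RunConfig,
    outcome_name: str,
    outcomes_df: pd.DataFrame,
    enc_df: pd.DataFrame,
    labels: pd.DataFrame,
    out_dir: Path,
) -> dict:
    series = timeseries.aggregate_monthly(
        outcomes_df, enc_df, labels, outcome_name, config.sim.go_live
    )
    io.write_table(series, out_dir / f"monthly_series_{outcome_name}.csv")
    posterior, draws, summary = causal_impact.estimate_impact(
        series, config.bsts, covariate_cols=timeseries.COVARIATE_COLUMNS
    )
    with open(out_dir / f"impact_summary_{outcome_name}.json", "w") as fh:
        json.dump(summary.to_dict(), fh, indent=2, sort_keys=True)
    if config.render_plots:
        causal_impact.render_impact_panels(
            series, posterior, draws, out_dir / f"impact_panels_{outcome_name}.png",
            ci_level=config.bsts.ci_level,
        )
    pre = series[series["period"] == "pre"]
    pre_value = float((pre["y"] * pre["n"]).sum() / pre["n"].sum())
    lo, hi = summary.counterfactual_ci
    return {
        "outcome": outcome_name,
        "pre_value": pre_value,
        "expected_post": summary.counterfactual_mean,
        "ci_low": lo,
        "ci_high": hi,
        "actual_post": summary.observed_post_mean,
        "significant": int(not (lo <= summary.observed_post_mean <= hi)),
        "tail_probability": summary.tail_probability,
    }


@_stage("associate")
def stage_associate(outcomes_df, enc_df, labels, out_dir: Path):
    fit = fit_time_to_abx_model(outcomes_df, enc_df, labels)
    io.write_table(fit.to_frame(), out_dir / "association_table.csv")
    return fit


def run_pipeline(config: RunConfig) -> pd.DataFrame:
    """Execute every stage; returns the per-outcome summary report table."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    encounters, enc_df, ev_df = stage_simulate(config, out_dir)
    labels = stage_phenotype(encounters, out_dir)
    outcomes_df = stage_outcomes(encounters, labels, out_dir)

    rows = []
    for name in config.outcome_names:
        rows.append(stage_impact(config, name, outcomes_df, enc_df, labels, out_dir))
    report = pd.DataFrame(rows)
    io.write_table(report, out_dir / "summary_report.csv")

    try:
        stage_associate(outcomes_df, enc_df, labels, out_dir)
    except PipelineError as exc:
        logger.warning("association stage skipped: %s", exc)

    return report
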