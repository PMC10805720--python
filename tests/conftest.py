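"""Shared fixtures: a reduced-scale synthetic cohort reused across test modules.

The study calendar (2021-01-01 .. 2023-04-30, go-live 2022-12-07) is kept;
volume is scaled down and septic prevalence scaled up so each month still
carries a realistic septic count while generation stays fast.
"""

from __future__ import annotations

import pytest

from sepsis_impact import adjudicate_cohort, derive_outcomes, simulate
from sepsis_impact.records import encounters_to_frame, events_to_frame
from sepsis_impact.synthetic_ehr import SimConfig


def small_sim_config(seed: int = 7, **overrides) -> SimConfig:
    params = dict(monthly_volume_per_site=150, sepsis_prevalence=0.30, seed=seed)
    params.update(overrides)
    return SimConfig(**params)


@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    return small_sim_config()


@pytest.fixture(scope="session")
def cohort(sim_config):
    return simulate(sim_config)


@pytest.fixture(scope="session")
def cohort_frames(cohort):
    return encounters_to_frame(cohort), events_to_frame(cohort)


@pytest.fixture(scope="session")
def labels(cohort):
    return adjudicate_cohort(cohort)


@pytest.fixture(scope="session")
def outcomes_df(cohort, labels):
    return derive_outcomes(cohort, labels)
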