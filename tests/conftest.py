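from __future__ import annotations

from datetime import date, timedelta

import pytest

from hipps.concept_registry import HierarchyConfig, default_registry
from hipps.ehr_model import ClinicalEvent
from hipps.pipeline_cli import run_hipps
from hipps.synth_cohort import SimConfig, simulate_cohort

D0 = date(2020, 1, 1)


def day(n: int) -> date:
    """Day offset from the shared test epoch."""
    return D0 + timedelta(days=n)


def mk_event(
    person_id: str,
    event_date: date,
    concept_id: int,
    domain: str = "observation",
    concept_name: str = "",
    value: str = "",
) -> ClinicalEvent:
    return ClinicalEvent(
        person_id=person_id,
        event_date=event_date,
        concept_id=concept_id,
        domain=domain,
        concept_name=concept_name,
        value=value,
    )


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def hconfig(registry) -> HierarchyConfig:
    return registry.hierarchy


@pytest.fixture(scope="session")
def clean_sim(registry):
    """Small noise-free cohort shared by recovery-style tests."""
    config = SimConfig(
        random_seed=7,
        n_persons=60,
        pregnancies_per_person={1: 0.7, 2: 0.3},
        covid_screen_rate=0.4,
        covid_positive_rate=0.1,
    )
    return config, simulate_cohort(config, registry)


@pytest.fixture(scope="session")
def clean_run(clean_sim, registry):
    _, result = clean_sim
    return result, run_hipps(result.events, registry)
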