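"""Seeded synthetic OMOP-lite cohorts with hidden ground-truth pregnancies.

The generator emits, per pregnancy: week-resolution gestation records at the
configured visit schedule (exactly at ``true_lmp + 7*week`` days, so
noise-free recovery is exact), ranged timing events drawn uniformly inside
each concept's expected gestational-month window, outcome records at the
outcome date, and optional COVID-19 test/diagnosis events.  Inter-pregnancy
gaps respect the retry and outcome-separation rules so the ground truth is
recoverable by construction.  :func:`corrupt_events` layers reproducible
noise (gestation-week dropout, outlier gestation records whose implied start
deviates by more than 28 days, historical records outside any pregnancy) on
top of a clean simulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Mapping, Optional, Sequence

import numpy as np

from .concept_registry import (
    ConceptRegistry,
    MAX_GESTATION_WEEK,
    OutcomeCategory,
    TimingUsage,
    gw_concept_name,
)
from .ehr_model import ClinicalEvent, EventTable, PersonRecord

__all__ = [
    "GroundTruthPregnancy",
    "SimConfig",
    "SimResult",
    "simulate_cohort",
    "corrupt_events",
    "write_sim_result",
]


class SimConfigError(ValueError):
    """The simulation configuration is infeasible or inconsistent."""


@dataclass(frozen=True)
class GroundTruthPregnancy:
    """The simulator's hidden truth for one pregnancy."""

    person_id: str
    true_lmp: date
    outcome_category: Optional[OutcomeCategory]
    outcome_date: Optional[date]
    gestational_length_days: int

    def __post_init__(self) -> None:
        if self.outcome_category is not None:
            expected = self.true_lmp + timedelta(days=self.gestational_length_days)
            assert self.outcome_date == expected


# Per-category gestational length draw: (mean, sd, lo, hi), truncated.
# Live-birth/delivery lengths peak at 273 days (39 weeks).  Lower bounds sit
# above 35 days so every pregnancy emits at least one early timing event.
_LENGTH_PARAMS: dict[Optional[OutcomeCategory], tuple[float, float, int, int]] = {
    OutcomeCategory.LIVE_BIRTH: (273.0, 9.0, 221, 300),
    OutcomeCategory.STILLBIRTH: (245.0, 25.0, 170, 300),
    OutcomeCategory.ECTOPIC: (56.0, 12.0, 35, 84),
    OutcomeCategory.SPONTANEOUS_ABORTION: (70.0, 25.0, 35, 160),
    OutcomeCategory.INDUCED_ABORTION: (77.0, 25.0, 35, 160),
    OutcomeCategory.DELIVERY_ONLY: (273.0, 9.0, 221, 300),
    None: (273.0, 9.0, 221, 300),
}


def _default_outcome_mix() -> dict[Optional[OutcomeCategory], float]:
    return {
        OutcomeCategory.LIVE_BIRTH: 0.55,
        OutcomeCategory.STILLBIRTH: 0.05,
        OutcomeCategory.ECTOPIC: 0.05,
        OutcomeCategory.SPONTANEOUS_ABORTION: 0.08,
        OutcomeCategory.INDUCED_ABORTION: 0.05,
        OutcomeCategory.DELIVERY_ONLY: 0.12,
        None: 0.10,
    }


@dataclass(frozen=True)
class SimConfig:
    random_seed: int
    n_persons: int = 100
    pregnancies_per_person: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.7, 2: 0.3}
    )
    outcome_mix: Mapping[Optional[OutcomeCategory], float] = field(
        default_factory=_default_outcome_mix
    )
    visit_schedule: tuple[int, ...] = (8, 12, 16, 20, 24, 28, 32, 36)
    p_missing_outcome: float = 0.0
    p_duplicate_outcome: float = 0.0
    p_missing_gw: float = 0.0
    p_outlier_gw: float = 0.0
    p_historical: float = 0.0
    covid_screen_rate: float = 0.0
    covid_positive_rate: float = 0.0
    gw_jitter_days: int = 0
    lmp_range: tuple[date, date] = (date(2018, 6, 1), date(2021, 6, 1))
    inter_pregnancy_gap_days: tuple[int, int] = (200, 420)

    def __post_init__(self) -> None:
        if self.random_seed is None:
            raise SimConfigError("random_seed is mandatory")
        for name in (
            "p_missing_outcome",
            "p_duplicate_outcome",
            "p_missing_gw",
            "p_outlier_gw",
            "p_historical",
            "covid_screen_rate",
            "covid_positive_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimConfigError(f"{name}={v} outside [0, 1]")
        for mapping, label in (
            (self.pregnancies_per_person, "pregnancies_per_person"),
            (self.outcome_mix, "outcome_mix"),
        ):
            total = sum(mapping.values())
            if abs(total - 1.0) > 1e-9:
                raise SimConfigError(f"{label} probabilities sum to {total}, not 1")
            if any(p < 0 for p in mapping.values()):
                raise SimConfigError(f"{label} has negative probability")
        if not 0 <= self.gw_jitter_days <= 3:
            raise SimConfigError("gw_jitter_days must be in [0, 3]")
        if any(k < 0 for k in self.pregnancies_per_person):
            raise SimConfigError("pregnancy counts must be non-negative")
        lo, hi = self.inter_pregnancy_gap_days
        if lo < 184 or hi < lo:
            # Gaps below ~6 months can place a subsequent LMP too close for
            # the retry/separation rules to keep the truth recoverable.
            raise SimConfigError(
                "inter_pregnancy_gap_days must satisfy 184 <= lo <= hi"
            )
        for cat in self.outcome_mix:
            if cat is not None and not isinstance(cat, OutcomeCategory):
                raise SimConfigError(f"outcome_mix key {cat!r} is not a category")


@dataclass(frozen=True)
class SimResult:
    persons: tuple[PersonRecord, ...]
    events: EventTable
    truth: tuple[GroundTruthPregnancy, ...]


def _draw_choice(rng: np.random.Generator, mapping: Mapping) -> object:
    keys = list(mapping.keys())
    probs = np.array([mapping[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    return keys[int(rng.choice(len(keys), p=probs))]


def _draw_length(
    rng: np.random.Generator, category: Optional[OutcomeCategory]
) -> int:
    mean, sd, lo, hi = _LENGTH_PARAMS[category]
    for _ in range(1000):
        draw = int(round(rng.normal(mean, sd)))
        if lo <= draw <= hi:
            return draw
    return int(np.clip(round(mean), lo, hi))  # pragma: no cover - safety net


def simulate_cohort(config: SimConfig, registry: ConceptRegistry) -> SimResult:
    """Generate persons, events, and ground truth; reproducible from seed."""
    for usage in TimingUsage:
        if not registry.timing_by_usage(usage):
            raise SimConfigError(f"registry has no {usage.value} timing concepts")
    if not registry.gestation_weeks or not registry.outcomes:
        raise SimConfigError("registry must contain GW and outcome concepts")

    rng = np.random.default_rng(config.random_seed)
    dpm = registry.hierarchy.days_per_month
    outcome_concepts: dict[OutcomeCategory, tuple[int, ...]] = {}
    for cid, cat in sorted(registry.outcomes.items()):
        outcome_concepts.setdefault(cat, ())
        outcome_concepts[cat] = outcome_concepts[cat] + (cid,)
    gw_ids = {gw.week: cid for cid, gw in registry.gestation_weeks.items()}
    covid_test = sorted(registry.covid.pcr_ag_test)
    covid_dx = sorted(registry.covid.covid_diagnosis)

    persons: list[PersonRecord] = []
    events: list[ClinicalEvent] = []
    truth: list[GroundTruthPregnancy] = []
    lmp_lo, lmp_hi = config.lmp_range
    lmp_span = (lmp_hi - lmp_lo).days
    if lmp_span < 0:
        raise SimConfigError("lmp_range must be non-decreasing")

    for idx in range(config.n_persons):
        person_id = f"P{idx + 1:06d}"
        n_preg = int(_draw_choice(rng, config.pregnancies_per_person))
        first_lmp = lmp_lo + timedelta(days=int(rng.integers(0, lmp_span + 1)))
        age_years = int(rng.integers(18, 41))
        birth_date = first_lmp - timedelta(
            days=age_years * 365 + int(rng.integers(0, 365))
        )
        persons.append(
            PersonRecord(
                person_id=person_id,
                birth_date=birth_date,
                sex="female",
                race="unknown",
                ethnicity="unknown",
            )
        )
        lmp = first_lmp
        for _ in range(n_preg):
            category = _draw_choice(rng, config.outcome_mix)
            length = _draw_length(rng, category)
            outcome_date = (
                lmp + timedelta(days=length) if category is not None else None
            )
            truth.append(
                GroundTruthPregnancy(
                    person_id=person_id,
                    true_lmp=lmp,
                    outcome_category=category,
                    outcome_date=outcome_date,
                    gestational_length_days=length,
                )
            )
            events.extend(
                _pregnancy_events(
                    rng,
                    config,
                    registry,
                    person_id,
                    lmp,
                    length,
                    category,
                    outcome_concepts,
                    gw_ids,
                    covid_test,
                    covid_dx,
                    dpm,
                )
            )
            gap_lo, gap_hi = config.inter_pregnancy_gap_days
            lmp = lmp + timedelta(
                days=length + int(rng.integers(gap_lo, gap_hi + 1))
            )
    return SimResult(
        persons=tuple(persons), events=EventTable(events), truth=tuple(truth)
    )


def _pregnancy_events(
    rng: np.random.Generator,
    config: SimConfig,
    registry: ConceptRegistry,
    person_id: str,
    lmp: date,
    length: int,
    category: Optional[OutcomeCategory],
    outcome_concepts: dict[OutcomeCategory, tuple[int, ...]],
    gw_ids: dict[int, int],
    covid_test: Sequence[int],
    covid_dx: Sequence[int],
    dpm: float,
) -> list[ClinicalEvent]:
    events: list[ClinicalEvent] = []
    # Dates that bound the recorded episode (week-level, progression, and
    # outcome records); held-out events are confined to this span so a clean
    # simulation yields 100% in-episode overlap.
    anchor_dates: list[date] = []
    # Week-level gestation records at the visit schedule.
    for week in config.visit_schedule:
        if 7 * week > length or week not in gw_ids:
            continue
        jitter = (
            int(rng.integers(-config.gw_jitter_days, config.gw_jitter_days + 1))
            if config.gw_jitter_days
            else 0
        )
        gw_event = ClinicalEvent(
            person_id=person_id,
            event_date=lmp + timedelta(days=7 * week + jitter),
            concept_id=gw_ids[week],
            domain="observation",
            concept_name=gw_concept_name(week),
        )
        events.append(gw_event)
        anchor_dates.append(gw_event.event_date)
    # Ranged timing events, drawn uniformly inside each feasible window.
    domains = {
        TimingUsage.PROGRESSION: "procedure",
        TimingUsage.GR3M: "measurement",
        TimingUsage.HELD_OUT: "condition",
    }
    held_out_pending: list = []
    for usage in (TimingUsage.PROGRESSION, TimingUsage.GR3M, TimingUsage.HELD_OUT):
        for tc in registry.timing_by_usage(usage):
            lo = math.ceil(tc.min_month * dpm)
            hi = math.floor(min(tc.max_month * dpm, float(length)))
            if lo > hi:
                continue
            if usage is TimingUsage.HELD_OUT:
                held_out_pending.append((tc, lo, hi))
                continue
            offset = int(rng.integers(lo, hi + 1))
            timed = ClinicalEvent(
                person_id=person_id,
                event_date=lmp + timedelta(days=offset),
                concept_id=tc.concept_id,
                domain=domains[usage],
                concept_name=tc.concept_name,
            )
            events.append(timed)
            if usage is TimingUsage.PROGRESSION:
                anchor_dates.append(timed.event_date)
    # Outcome record(s).
    if category is not None and rng.random() >= config.p_missing_outcome:
        cids = outcome_concepts[category]
        outcome_date = lmp + timedelta(days=length)
        anchor_dates.append(outcome_date)
        events.append(
            ClinicalEvent(
                person_id=person_id,
                event_date=outcome_date,
                concept_id=cids[0],
                domain="condition",
                concept_name=category.value.lower().replace("_", " "),
            )
        )
        if len(cids) > 1 and rng.random() < config.p_duplicate_outcome:
            events.append(
                ClinicalEvent(
                    person_id=person_id,
                    event_date=outcome_date,
                    concept_id=cids[1],
                    domain="condition",
                    concept_name=category.value.lower().replace("_", " "),
                )
            )
    # COVID-19 testing: positives are screened by construction.
    screened = rng.random() < config.covid_screen_rate
    positive = rng.random() < config.covid_positive_rate
    if (screened or positive) and covid_test:
        day_hi = max(2, length - 7)
        test_day = int(rng.integers(1, day_hi))
        test_date = lmp + timedelta(days=test_day)
        events.append(
            ClinicalEvent(
                person_id=person_id,
                event_date=test_date,
                concept_id=covid_test[0],
                domain="measurement",
                concept_name="SARS-CoV-2 PCR/Ag test",
                value="positive" if positive else "negative",
            )
        )
        if positive and covid_dx:
            events.append(
                ClinicalEvent(
                    person_id=person_id,
                    event_date=test_date,
                    concept_id=covid_dx[0],
                    domain="condition",
                    concept_name="COVID-19 diagnosis",
                )
            )
    # Held-out validation events, confined to the episode-bounding span.
    if anchor_dates:
        horizon = (max(anchor_dates) - lmp).days
        for tc, lo, hi in held_out_pending:
            hi = min(hi, horizon)
            if lo > hi:
                continue
            offset = int(rng.integers(lo, hi + 1))
            events.append(
                ClinicalEvent(
                    person_id=person_id,
                    event_date=lmp + timedelta(days=offset),
                    concept_id=tc.concept_id,
                    domain=domains[TimingUsage.HELD_OUT],
                    concept_name=tc.concept_name,
                )
            )
    return events


def corrupt_events(
    events: EventTable, config: SimConfig, registry: ConceptRegistry
) -> EventTable:
    """Apply seeded noise to a clean event stream; the input is untouched.

    Noise channels: gestation-week dropout (``p_missing_gw``), outlier
    gestation-week insertion (``p_outlier_gw``; the inserted record's
    back-projected start deviates from the source record's by >28 days), and
    historical-record insertion (``p_historical``; one gestation record dated
    long before the person's first event).  Uses an independent stream
    derived from ``random_seed`` so simulation draws are unaffected.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.random_seed, 0xC0]))
    out: list[ClinicalEvent] = []
    first_event_by_person: dict[str, date] = {}
    for ev in events:
        cur = first_event_by_person.get(ev.person_id)
        if cur is None or ev.event_date < cur:
            first_event_by_person[ev.person_id] = ev.event_date
    gw_ids = {gw.week: cid for cid, gw in registry.gestation_weeks.items()}

    for ev in events:
        week = registry.week_for(ev.concept_id)
        if week is None:
            out.append(ev)
            continue
        if config.p_missing_gw and rng.random() < config.p_missing_gw:
            continue
        out.append(ev)
        if config.p_outlier_gw and rng.random() < config.p_outlier_gw:
            shift_days = int(rng.integers(1, 7))
            delta = int(rng.integers(5, 17)) * (1 if rng.random() < 0.5 else -1)
            new_week = week + delta
            if not 1 <= new_week <= MAX_GESTATION_WEEK:
                new_week = week - delta
            if not 1 <= new_week <= MAX_GESTATION_WEEK or new_week == week:
                continue
            out.append(
                ClinicalEvent(
                    person_id=ev.person_id,
                    event_date=ev.event_date + timedelta(days=shift_days),
                    concept_id=gw_ids[new_week],
                    domain="observation",
                    concept_name=gw_concept_name(new_week),
                )
            )
    if config.p_historical:
        for person_id in sorted(first_event_by_person):
            if rng.random() < config.p_historical:
                week = int(rng.integers(4, 31))
                back = int(rng.integers(400, 701))
                out.append(
                    ClinicalEvent(
                        person_id=person_id,
                        event_date=first_event_by_person[person_id]
                        - timedelta(days=back),
                        concept_id=gw_ids[week],
                        domain="observation",
                        concept_name=gw_concept_name(week),
                    )
                )
    return EventTable(out)


def write_sim_result(result: SimResult, out_dir) -> None:
    """Write persons/events/truth as OMOP-lite CSVs plus truth.csv."""
    import csv
    from pathlib import Path

    from .ehr_model import TABLE_FILENAMES, write_persons

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_persons(result.persons, out_dir / "person.csv")

    headers = {
        "condition": ("condition_concept_id", "condition_start_date", "condition_concept_name"),
        "procedure": ("procedure_concept_id", "procedure_date", "procedure_concept_name"),
        "observation": ("observation_concept_id", "observation_date", "observation_concept_name"),
        "measurement": ("measurement_concept_id", "measurement_date", "measurement_concept_name"),
        "drug": ("drug_concept_id", "drug_exposure_start_date", "drug_concept_name"),
    }
    by_domain: dict[str, list[ClinicalEvent]] = {d: [] for d in headers}
    for ev in result.events:
        by_domain[ev.domain].append(ev)
    for domain, evs in by_domain.items():
        id_col, date_col, name_col = headers[domain]
        cols = ["person_id", id_col, date_col, name_col]
        if domain == "measurement":
            cols.append("value_source_value")
        with open(out_dir / TABLE_FILENAMES[domain], "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(cols)
            for ev in evs:
                row = [ev.person_id, ev.concept_id, ev.event_date.isoformat(), ev.concept_name]
                if domain == "measurement":
                    row.append(ev.value)
                writer.writerow(row)
    with open(out_dir / "truth.csv", "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            [
                "person_id",
                "true_lmp",
                "outcome_category",
                "outcome_date",
                "gestational_length_days",
            ]
        )
        for t in result.truth:
            writer.writerow(
                [
                    t.person_id,
                    t.true_lmp.isoformat(),
                    t.outcome_category.value if t.outcome_category else "",
                    t.outcome_date.isoformat() if t.outcome_date else "",
                    t.gestational_length_days,
                ]
            )
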