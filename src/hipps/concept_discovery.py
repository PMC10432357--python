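"""Data-driven derivation of pregnancy-specific and timing concepts.

Two analyses, both re-runnable on synthetic or real extracts:

* frequency enrichment — concepts present in enough case persons and
  sufficiently more frequent (person-level presence, not event counts)
  among cases than controls;
* timing statistics — mean/SD of when each candidate concept occurs
  relative to rule-based episode starts, filtered at SD < 1.5 months.

The clinician step of assigning expected min/max gestational months is
modeled as an editable curation CSV emitted by :func:`write_curation_template`
and re-imported with :func:`import_curation`, which enforces the
span <= 3 months rule on import.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .concept_registry import (
    ConceptRegistry,
    RegistryError,
    TimingConcept,
    TimingUsage,
)
from .ehr_model import EventTable
from .hip import HipEpisode

__all__ = [
    "ConceptEnrichmentRow",
    "ConceptTimingStats",
    "enrich_concepts",
    "timing_statistics",
    "write_curation_template",
    "import_curation",
]


@dataclass(frozen=True)
class ConceptEnrichmentRow:
    concept_id: int
    n_case_persons: int
    case_rate: float
    control_rate: float
    fold: float  # case_rate / control_rate; +inf when absent in controls


@dataclass(frozen=True)
class ConceptTimingStats:
    concept_id: int
    mean_offset_months: float
    sd_offset_months: float
    n_observations: int
    is_candidate: bool


def enrich_concepts(
    events: EventTable,
    case_ids: set[str],
    control_ids: set[str],
    min_persons: int = 1000,
    min_fold: float = 10.0,
) -> list[ConceptEnrichmentRow]:
    """Concepts enriched among case persons, by person-level presence.

    Rates are the fraction of case/control persons with at least one
    occurrence, so duplicated events within a person cannot change the
    result.  Concepts absent from controls get infinite fold and are kept
    whenever the person threshold is met.
    """
    if not case_ids or not control_ids:
        raise ValueError("case and control id sets must be nonempty")
    if case_ids & control_ids:
        raise ValueError("case and control id sets must be disjoint")
    case_presence: dict[int, set[str]] = {}
    control_presence: dict[int, set[str]] = {}
    for ev in events:
        if ev.person_id in case_ids:
            case_presence.setdefault(ev.concept_id, set()).add(ev.person_id)
        elif ev.person_id in control_ids:
            control_presence.setdefault(ev.concept_id, set()).add(ev.person_id)
    rows: list[ConceptEnrichmentRow] = []
    for concept_id in sorted(case_presence):
        n_case = len(case_presence[concept_id])
        if n_case < min_persons:
            continue
        case_rate = n_case / len(case_ids)
        control_rate = len(control_presence.get(concept_id, ())) / len(control_ids)
        fold = case_rate / control_rate if control_rate > 0 else math.inf
        if fold >= min_fold:
            rows.append(
                ConceptEnrichmentRow(
                    concept_id=concept_id,
                    n_case_persons=n_case,
                    case_rate=case_rate,
                    control_rate=control_rate,
                    fold=fold,
                )
            )
    return rows


def timing_statistics(
    events: EventTable,
    hip_episodes: Sequence[HipEpisode],
    registry: ConceptRegistry,
    max_sd_months: float = 1.5,
    candidate_concepts: Optional[set[int]] = None,
) -> list[ConceptTimingStats]:
    """Mean/SD of concept occurrence relative to episode starts, in months.

    Only events inside an episode with an outcome contribute; offsets are
    measured from the episode start in ``days_per_month`` units.  Sample
    (n-1) standard deviation is used; rows need >= 2 observations for a
    defined SD and are flagged as timing candidates below ``max_sd_months``.
    Gestation-week and outcome concepts are never candidates.
    """
    dpm = registry.hierarchy.days_per_month
    excluded = set(registry.gestation_weeks) | set(registry.outcomes)
    eps_by_person: dict[str, list[HipEpisode]] = {}
    for ep in hip_episodes:
        if ep.outcome_category is not None:
            eps_by_person.setdefault(ep.person_id, []).append(ep)
    offsets: dict[int, list[float]] = {}
    for ev in events:
        if ev.concept_id in excluded:
            continue
        if candidate_concepts is not None and ev.concept_id not in candidate_concepts:
            continue
        for ep in eps_by_person.get(ev.person_id, ()):
            if ep.start_date <= ev.event_date <= ep.end_date:
                offsets.setdefault(ev.concept_id, []).append(
                    (ev.event_date - ep.start_date).days / dpm
                )
                break
    stats: list[ConceptTimingStats] = []
    for concept_id in sorted(offsets):
        xs = offsets[concept_id]
        n = len(xs)
        mean = sum(xs) / n
        if n >= 2:
            sd = math.sqrt(sum((x - mean) ** 2 for x in xs) / (n - 1))
        else:
            sd = math.nan
        stats.append(
            ConceptTimingStats(
                concept_id=concept_id,
                mean_offset_months=mean,
                sd_offset_months=sd,
                n_observations=n,
                is_candidate=bool(n >= 2 and sd < max_sd_months),
            )
        )
    return stats


_CURATION_COLUMNS = (
    "concept_id",
    "mean_offset_months",
    "sd_offset_months",
    "n_observations",
    "min_month",
    "max_month",
    "usage",
)


def write_curation_template(
    stats: Iterable[ConceptTimingStats], path: str | Path
) -> None:
    """Emit an editable CSV of timing candidates for window assignment.

    Reviewers fill in ``min_month``/``max_month``/``usage`` per concept;
    the file is then re-imported with :func:`import_curation`.
    """
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CURATION_COLUMNS)
        for s in stats:
            if not s.is_candidate:
                continue
            writer.writerow(
                [
                    s.concept_id,
                    f"{s.mean_offset_months:.3f}",
                    f"{s.sd_offset_months:.3f}",
                    s.n_observations,
                    "",
                    "",
                    "",
                ]
            )


def import_curation(path: str | Path) -> list[TimingConcept]:
    """Read a filled curation CSV back into validated timing concepts.

    Rows without assigned windows are skipped; a window whose span exceeds
    the limit for its usage (3 months for progression/GR3m) is rejected.
    """
    concepts: list[TimingConcept] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            if not row.get("min_month") or not row.get("max_month"):
                continue
            usage_raw = (row.get("usage") or TimingUsage.PROGRESSION.value).strip()
            try:
                usage = TimingUsage(usage_raw)
            except ValueError as exc:
                raise RegistryError(
                    f"concept {row['concept_id']}: unknown usage {usage_raw!r}"
                ) from exc
            concepts.append(
                TimingConcept(
                    concept_id=int(row["concept_id"]),
                    min_month=float(row["min_month"]),
                    max_month=float(row["max_month"]),
                    usage=usage,
                )
            )
    return concepts
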