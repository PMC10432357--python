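"""Post-episode annotation: COVID-19 status, analysis cohorts, QC overlap.

Episodes are annotated with in-episode COVID-19 positivity/screening and the
60-day reinfection rule, assigned to three nested-by-strictness analysis
cohorts (all episodes; outcome + month-or-better start precision; outcome +
concordance score 2 + week precision), stratified around March 1 2020 by
episode *end* date, and flagged as likely-ongoing when an outcome-less
episode has not yet reached the plausible delivery window.  A held-out
concept overlap table provides external validation of episode placement.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta
from typing import Iterable, Optional, Sequence

from .concept_registry import ConceptRegistry, HierarchyConfig, OutcomeCategory
from .ehr_model import ClinicalEvent, EventTable
from .episode_merge import HippsEpisode

__all__ = [
    "EpisodeAnnotation",
    "covid_status",
    "assign_cohorts",
    "flag_ongoing",
    "annotate_episodes",
    "heldout_overlap",
    "PANDEMIC_SPLIT_DATE",
]

PANDEMIC_SPLIT_DATE = date(2020, 3, 1)

#: Qualitative lab values treated as positive (case-insensitive).
POSITIVE_VALUES = frozenset({"positive", "detected"})

#: Start precision levels admitting an episode to the month-level cohort
#: (week-level poor support included by definition).
_MONTH_OR_BETTER = frozenset(
    {"week", "week_poor-support", "two-week", "three-week", "month"}
)


@dataclass
class EpisodeAnnotation:
    episode_id: str
    covid_positive: bool = False
    covid_index_date: Optional[date] = None
    covid_screened: bool = False
    reinfection: bool = False
    stratum: str = "pre_2020-03-01"
    cohort1: bool = True
    cohort2: bool = False
    cohort3: bool = False
    ongoing: bool = False


def _is_positive_test(ev: ClinicalEvent, registry: ConceptRegistry) -> bool:
    return (
        ev.concept_id in registry.covid.pcr_ag_test
        and ev.value.strip().lower() in POSITIVE_VALUES
    )


def covid_status(
    events: Iterable[ClinicalEvent],
    episode: HippsEpisode,
    registry: ConceptRegistry,
    reinfection_gap_days: int = 60,
) -> tuple[bool, Optional[date], bool, bool]:
    """(covid_positive, covid_index_date, covid_screened, reinfection).

    A qualifying positive is a positive PCR/antigen result or a diagnosis
    code; the first one inside [start, end] sets the index date.  Screening
    counts any PCR/Ag test in-episode regardless of result.  Reinfection is
    any in-episode qualifying positive at least ``reinfection_gap_days``
    after the index.
    """
    start, end = episode.start_date, episode.end_date
    in_episode = [
        ev
        for ev in events
        if ev.person_id == episode.person_id and start <= ev.event_date <= end
    ]
    screened = any(
        ev.concept_id in registry.covid.pcr_ag_test for ev in in_episode
    )
    positives = sorted(
        {
            ev.event_date
            for ev in in_episode
            if _is_positive_test(ev, registry)
            or ev.concept_id in registry.covid.covid_diagnosis
        }
    )
    if not positives:
        return False, None, screened, False
    index = positives[0]
    reinfection = any(
        (d - index).days >= reinfection_gap_days for d in positives[1:]
    )
    return True, index, screened, reinfection


def assign_cohorts(
    episode: HippsEpisode, covid_positive: bool
) -> tuple[bool, bool, bool, str]:
    """(cohort1, cohort2, cohort3, stratum) for one scored episode."""
    has_outcome = (
        episode.outcome_category is not None
        and episode.outcome_category is not OutcomeCategory.DELIVERY_ONLY
    )
    precision = episode.precision_category or "non-specific"
    cohort2 = has_outcome and precision in _MONTH_OR_BETTER
    cohort3 = (
        has_outcome and episode.concordance_score == 2 and precision == "week"
    )
    if episode.end_date < PANDEMIC_SPLIT_DATE:
        stratum = "pre_2020-03-01"
    elif covid_positive:
        stratum = "covid_pos_post"
    else:
        stratum = "covid_neg_post"
    return True, cohort2, cohort3, stratum


def flag_ongoing(
    episode: HippsEpisode, as_of: date, config: HierarchyConfig
) -> bool:
    """True when an outcome-less episode has not yet reached the earliest
    plausible delivery length; episodes with an outcome are never ongoing."""
    if episode.outcome_category is not None:
        return False
    start = episode.inferred_start_date or episode.start_date
    if start is None:
        return False
    return (as_of - start).days < config.min_delivery_days


def annotate_episodes(
    events: EventTable,
    episodes: Sequence[HippsEpisode],
    registry: ConceptRegistry,
    as_of: Optional[date] = None,
) -> list[EpisodeAnnotation]:
    if as_of is None:
        as_of = max((e.event_date for e in events), default=date.today())
    by_person = events.by_person()
    annotations: list[EpisodeAnnotation] = []
    for ep in episodes:
        person_events = by_person.get(ep.person_id, [])
        positive, index, screened, reinf = covid_status(person_events, ep, registry)
        c1, c2, c3, stratum = assign_cohorts(ep, positive)
        annotations.append(
            EpisodeAnnotation(
                episode_id=ep.episode_id,
                covid_positive=positive,
                covid_index_date=index,
                covid_screened=screened,
                reinfection=reinf,
                stratum=stratum,
                cohort1=c1,
                cohort2=c2,
                cohort3=c3,
                ongoing=flag_ongoing(ep, as_of, registry.hierarchy),
            )
        )
    return annotations


def heldout_overlap(
    events: EventTable,
    episodes: Sequence[HippsEpisode],
    registry: ConceptRegistry,
) -> dict[int, float]:
    """Per held-out concept: % of occurrences inside an episode *and* inside
    the concept's expected gestational window from the inferred start.

    Concepts with zero occurrences are omitted.
    """
    dpm = registry.hierarchy.days_per_month
    held_out = {tc.concept_id: tc for tc in registry.held_out_concepts}
    eps_by_person: dict[str, list[HippsEpisode]] = {}
    for ep in episodes:
        eps_by_person.setdefault(ep.person_id, []).append(ep)
    totals: dict[int, int] = {}
    hits: dict[int, int] = {}
    for ev in events:
        tc = held_out.get(ev.concept_id)
        if tc is None:
            continue
        totals[tc.concept_id] = totals.get(tc.concept_id, 0) + 1
        for ep in eps_by_person.get(ev.person_id, ()):
            if not (ep.start_date <= ev.event_date <= ep.end_date):
                continue
            anchor = ep.inferred_start_date or ep.start_date
            offset_months = (ev.event_date - anchor).days / dpm
            if tc.min_month <= offset_months <= tc.max_month:
                hits[tc.concept_id] = hits.get(tc.concept_id, 0) + 1
                break
    return {
        cid: 100.0 * hits.get(cid, 0) / total for cid, total in sorted(totals.items())
    }
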