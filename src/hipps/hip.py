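"""Hierarchy/rule-based episode construction from outcomes and gestation weeks.

Three stages, all per person:

1. ``assess_outcomes`` — keep only outcome records that respect the
   minimum-separation rules, processing categories in priority order
   (live birth > stillbirth > ectopic > spontaneous abortion > induced
   abortion > delivery-record-only).
2. ``infer_gestation_episodes`` — delineate gestation-based draft episodes
   from "Gestation period, X weeks" records: a week that fails to increase
   marks a potential new episode, accepted only if its back-projected start
   clears the previous draft; the draft's start is back-projected from its
   maximum week.
3. ``merge_hip`` — combine overlapping gestation drafts with outcomes,
   stripping outcomes whose gestational age is incompatible with the
   category's term-duration window; lone outcomes become episodes whose
   start is the maximum outcome-specific back-projection (301 days for a
   live birth).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta
from typing import Iterable, Optional, Sequence

from .concept_registry import HierarchyConfig, OutcomeCategory

__all__ = [
    "OutcomeEvent",
    "GestationDraftEpisode",
    "HipEpisode",
    "AuditRecord",
    "assess_outcomes",
    "infer_gestation_episodes",
    "merge_hip",
]

WEEK = timedelta(days=7)


@dataclass(frozen=True)
class OutcomeEvent:
    person_id: str
    event_date: date
    category: OutcomeCategory


@dataclass(frozen=True)
class GestationDraftEpisode:
    """A gestation-based draft delineated from GW records only."""

    person_id: str
    derived_start: date  # back-projected from the maximum-week record
    first_gw_date: date
    last_gw_date: date
    max_week: int

    def __post_init__(self) -> None:
        assert self.first_gw_date <= self.last_gw_date

    @property
    def span(self) -> tuple[date, date]:
        return (self.derived_start, self.last_gw_date)


@dataclass(frozen=True)
class HipEpisode:
    person_id: str
    start_date: date
    end_date: date
    outcome_category: Optional[OutcomeCategory]
    outcome_date: Optional[date]
    basis: str  # {"outcome_only", "gestation_only", "merged"}
    max_week: Optional[int] = None

    def overlaps(self, start: date, end: date) -> bool:
        # Closed-interval intersection of >= 1 day.
        return self.start_date <= end and start <= self.end_date


@dataclass(frozen=True)
class AuditRecord:
    """One dropped record with the rule that dropped it."""

    person_id: str
    event_date: date
    detail: str
    reason: str


def _group_by_person(events: Iterable) -> dict[str, list]:
    grouped: dict[str, list] = {}
    for e in events:
        grouped.setdefault(e.person_id, []).append(e)
    return grouped


# ---------------------------------------------------------------------------
# Outcome assessment
# ---------------------------------------------------------------------------


def assess_outcomes(
    events: Iterable[OutcomeEvent], config: HierarchyConfig
) -> tuple[list[OutcomeEvent], list[AuditRecord]]:
    """Retain outcome events that satisfy all minimum-separation rules.

    Categories are processed in priority order; within a category, events
    are scanned by date and an event is retained only if it is separated
    from *every* already-retained event (same or higher priority) by at
    least the configured minimum for the ordered category pair.  Duplicate
    same-category events on one date collapse to a single retained event.

    Idempotent: re-running on its own output returns it unchanged.
    """
    retained: list[OutcomeEvent] = []
    audit: list[AuditRecord] = []
    for person_id, person_events in sorted(_group_by_person(events).items()):
        kept: list[OutcomeEvent] = []
        for category in config.priority:
            in_cat = sorted(
                (e for e in person_events if e.category is category),
                key=lambda e: e.event_date,
            )
            for ev in in_cat:
                conflict = None
                for prior in kept:
                    if prior.event_date <= ev.event_date:
                        earlier, later = prior, ev
                    else:
                        earlier, later = ev, prior
                    gap = (later.event_date - earlier.event_date).days
                    required = config.min_separation(
                        earlier.category, later.category
                    )
                    if gap < required:
                        conflict = (prior, required, gap)
                        break
                if conflict is None:
                    kept.append(ev)
                else:
                    prior, required, gap = conflict
                    audit.append(
                        AuditRecord(
                            person_id=person_id,
                            event_date=ev.event_date,
                            detail=ev.category.value,
                            reason=(
                                f"separation {gap}d < {required}d from "
                                f"{prior.category.value}@{prior.event_date}"
                            ),
                        )
                    )
        kept.sort(key=lambda e: (e.event_date, e.category.priority))
        retained.extend(kept)
    return retained, audit


# ---------------------------------------------------------------------------
# Gestation-based drafts
# ---------------------------------------------------------------------------


def _close_draft(
    person_id: str, records: Sequence[tuple[date, int]]
) -> GestationDraftEpisode:
    max_week = max(w for _, w in records)
    # Back-project from the first record carrying the maximum week.
    max_date = next(d for d, w in records if w == max_week)
    return GestationDraftEpisode(
        person_id=person_id,
        derived_start=max_date - max_week * WEEK,
        first_gw_date=records[0][0],
        last_gw_date=records[-1][0],
        max_week=max_week,
    )


def infer_gestation_episodes(
    gw_events: Iterable[tuple[str, date, int]],
) -> tuple[list[GestationDraftEpisode], list[AuditRecord]]:
    """Delineate gestation-based drafts from (person_id, date, week) records.

    A record whose week fails to increase past the previous record's week is
    a potential episode split.  The split is accepted only when the record's
    back-projected start (date - 7*week) clears the running draft's span
    [derived_start, last record date]; otherwise the record is excluded as
    noise so a stale historical record cannot corrupt the back-projection.
    """
    drafts: list[GestationDraftEpisode] = []
    audit: list[AuditRecord] = []
    grouped = _group_by_person(
        [_Gw(person_id=p, event_date=d, week=w) for p, d, w in gw_events]
    )
    for person_id, records in sorted(grouped.items()):
        records.sort(key=lambda r: (r.event_date, r.week))
        current: list[tuple[date, int]] = []
        for rec in records:
            if not current:
                current.append((rec.event_date, rec.week))
                continue
            if rec.week > current[-1][1]:
                current.append((rec.event_date, rec.week))
                continue
            projected = rec.event_date - rec.week * WEEK
            draft_so_far = _close_draft(person_id, current)
            span_start, span_end = draft_so_far.span
            if span_start <= projected <= span_end:
                audit.append(
                    AuditRecord(
                        person_id=person_id,
                        event_date=rec.event_date,
                        detail=f"GW week {rec.week}",
                        reason=(
                            "projected start inside current draft "
                            f"[{span_start}..{span_end}]"
                        ),
                    )
                )
                continue
            drafts.append(draft_so_far)
            current = [(rec.event_date, rec.week)]
        if current:
            drafts.append(_close_draft(person_id, current))
    return drafts, audit


@dataclass(frozen=True)
class _Gw:
    person_id: str
    event_date: date
    week: int


# ---------------------------------------------------------------------------
# Merge of outcome-based and gestation-based episodes
# ---------------------------------------------------------------------------


def _term_aligned(
    max_week: int, category: OutcomeCategory, config: HierarchyConfig
) -> bool:
    lo, hi = config.term_window(category)
    return lo < max_week * 7 <= hi


def merge_hip(
    outcome_seq: Sequence[OutcomeEvent],
    gestation_drafts: Sequence[GestationDraftEpisode],
    config: HierarchyConfig,
) -> tuple[list[HipEpisode], list[AuditRecord]]:
    """Combine per-person outcome sequences with gestation drafts.

    An outcome whose outcome-based interval [date - term_max, date] overlaps
    a draft merges with it into one episode ending at the outcome date —
    unless the draft's maximum gestational age is incompatible with the
    outcome's term window, in which case the outcome is removed (eliminating
    misclassified outcomes) and the draft stays gestation-only.  Residual
    overlaps between back-projected starts are resolved by truncating the
    later episode's start, preserving one episode per retained outcome.
    """
    audit: list[AuditRecord] = []
    episodes: list[HipEpisode] = []
    persons = sorted(
        {e.person_id for e in outcome_seq} | {d.person_id for d in gestation_drafts}
    )
    outcomes_by_person = _group_by_person(outcome_seq)
    drafts_by_person = _group_by_person(gestation_drafts)
    for person_id in persons:
        outcomes = sorted(
            outcomes_by_person.get(person_id, []), key=lambda e: e.event_date
        )
        drafts = sorted(
            drafts_by_person.get(person_id, []), key=lambda d: d.derived_start
        )
        unconsumed = list(drafts)
        person_eps: list[HipEpisode] = []
        for outcome in outcomes:
            _, term_max = config.term_window(outcome.category)
            ob_start = outcome.event_date - timedelta(days=term_max)
            overlapping = [
                d
                for d in unconsumed
                if d.derived_start <= outcome.event_date
                and ob_start <= d.last_gw_date
            ]
            if overlapping:
                # Closest recorded end wins when several drafts overlap.
                draft = min(
                    overlapping,
                    key=lambda d: abs((d.last_gw_date - outcome.event_date).days),
                )
                unconsumed.remove(draft)
                if _term_aligned(draft.max_week, outcome.category, config):
                    person_eps.append(
                        HipEpisode(
                            person_id=person_id,
                            start_date=draft.derived_start,
                            end_date=outcome.event_date,
                            outcome_category=outcome.category,
                            outcome_date=outcome.event_date,
                            basis="merged",
                            max_week=draft.max_week,
                        )
                    )
                else:
                    audit.append(
                        AuditRecord(
                            person_id=person_id,
                            event_date=outcome.event_date,
                            detail=outcome.category.value,
                            reason=(
                                f"outcome removed: max GW {draft.max_week}w "
                                "incompatible with term window"
                            ),
                        )
                    )
                    person_eps.append(_gestation_only(draft))
            else:
                person_eps.append(
                    HipEpisode(
                        person_id=person_id,
                        start_date=ob_start,
                        end_date=outcome.event_date,
                        outcome_category=outcome.category,
                        outcome_date=outcome.event_date,
                        basis="outcome_only",
                    )
                )
        person_eps.extend(_gestation_only(d) for d in unconsumed)
        person_eps.sort(key=lambda e: (e.start_date, e.end_date))
        episodes.extend(_enforce_disjoint(person_eps, audit))
    episodes.sort(key=lambda e: (e.person_id, e.start_date))
    return episodes, audit


def _gestation_only(draft: GestationDraftEpisode) -> HipEpisode:
    # End of a gestation-only episode is the recorded span end; the inferred
    # end stays undefined until an outcome exists.
    return HipEpisode(
        person_id=draft.person_id,
        start_date=draft.derived_start,
        end_date=draft.last_gw_date,
        outcome_category=None,
        outcome_date=None,
        basis="gestation_only",
        max_week=draft.max_week,
    )


def _enforce_disjoint(
    episodes: list[HipEpisode], audit: list[AuditRecord]
) -> list[HipEpisode]:
    """Truncate back-projected starts so per-person episodes never overlap.

    Outcome-only starts are maximal back-projections, not observed data, so
    when one runs into the preceding episode it is clipped to the day after
    that episode ends.  An episode that cannot be clipped into a valid
    interval is dropped with an audit record (pathological inputs only).
    """
    result: list[HipEpisode] = []
    for ep in episodes:
        if result and ep.start_date <= result[-1].end_date:
            new_start = result[-1].end_date + timedelta(days=1)
            if new_start >= ep.end_date:
                audit.append(
                    AuditRecord(
                        person_id=ep.person_id,
                        event_date=ep.end_date,
                        detail=ep.basis,
                        reason="episode dropped: fully inside preceding episode",
                    )
                )
                continue
            ep = HipEpisode(
                person_id=ep.person_id,
                start_date=new_start,
                end_date=ep.end_date,
                outcome_category=ep.outcome_category,
                outcome_date=ep.outcome_date,
                basis=ep.basis,
                max_week=ep.max_week,
            )
        result.append(ep)
    return result
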