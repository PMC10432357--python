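"""Progression-signature episode building over timed clinical concepts.

The scan walks a person's dated progression events (each carrying an
expected gestational-month window) and asks, for every event, whether the
elapsed time to at least one earlier event of the running episode — or to
the immediately preceding event in the raw scan — is consistent with both
events' expected windows.  One consistent comparison extends the episode;
when all comparisons fail, a new episode starts only if the gap to the
previous event meets the 60-day retry period, otherwise the event is held
aside as unassigned noise.

Cleanup removes over-long episodes (>12 months) and all episodes of any
person with more than 5 episode starts inside a 365-day window.  Outcomes
are then attached by searching a window from 14 days before the episode end
up to the earlier of the next episode start and "10 months minus the last
record's expected minimum month" past the last record.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from datetime import date, timedelta
from typing import Iterable, Optional, Sequence

from .concept_registry import HierarchyConfig, OutcomeCategory
from .hip import OutcomeEvent

__all__ = [
    "ProgressionEvent",
    "PpsEpisode",
    "pair_compatible",
    "build_progressions",
    "cleanup",
    "attach_outcome",
    "attach_outcomes",
]


@dataclass(frozen=True)
class ProgressionEvent:
    person_id: str
    event_date: date
    concept_id: int
    min_month: float
    max_month: float


@dataclass(frozen=True)
class PpsEpisode:
    person_id: str
    events: tuple[ProgressionEvent, ...]
    outcome_category: Optional[OutcomeCategory] = None
    outcome_date: Optional[date] = None

    @property
    def first_event_date(self) -> date:
        return self.events[0].event_date

    @property
    def last_event_date(self) -> date:
        return self.events[-1].event_date

    @property
    def end_date(self) -> date:
        """Recorded end: outcome date when attached, else last event date."""
        if self.outcome_date is not None:
            return max(self.outcome_date, self.last_event_date)
        return self.last_event_date

    @property
    def recorded_length_days(self) -> int:
        return (self.last_event_date - self.first_event_date).days


def pair_compatible(
    a: ProgressionEvent, b: ProgressionEvent, days_per_month: float
) -> bool:
    """Is the elapsed time from ``a`` to ``b`` consistent with both windows?

    With ``a.event_date <= b.event_date``, the elapsed days must lie within
    [max(0, b.min_month - a.max_month), b.max_month - a.min_month] months.
    """
    if a.event_date > b.event_date:
        raise ValueError("pair_compatible requires a.event_date <= b.event_date")
    delta = (b.event_date - a.event_date).days
    lo = max(0.0, (b.min_month - a.max_month) * days_per_month)
    hi = (b.max_month - a.min_month) * days_per_month
    return lo <= delta <= hi


def build_progressions(
    events: Iterable[ProgressionEvent], config: HierarchyConfig
) -> tuple[list[PpsEpisode], list[ProgressionEvent]]:
    """Single deterministic scan building progression episodes per person.

    Returns (episodes, unassigned noise events).  Events failing every
    compatibility comparison with a gap below the retry period are excluded
    entirely rather than retroactively merged, keeping the pass single-scan.
    """
    dpm = config.days_per_month
    episodes: list[PpsEpisode] = []
    unassigned: list[ProgressionEvent] = []
    grouped: dict[str, list[ProgressionEvent]] = {}
    for e in events:
        grouped.setdefault(e.person_id, []).append(e)
    for person_id in sorted(grouped):
        seq = sorted(
            grouped[person_id], key=lambda e: (e.event_date, e.concept_id)
        )
        current: list[ProgressionEvent] = []
        prev: Optional[ProgressionEvent] = None
        for ev in seq:
            if not current:
                current = [ev]
                prev = ev
                continue
            # (1) against all members of the running episode, and (2) the
            # successive pair surrounding the event (its raw predecessor,
            # which may itself be unassigned noise).
            candidates = list(current)
            if prev is not None and prev not in candidates:
                candidates.append(prev)
            compatible = any(pair_compatible(c, ev, dpm) for c in candidates)
            if compatible:
                current.append(ev)
            else:
                gap = (ev.event_date - prev.event_date).days
                if gap >= config.retry_days:
                    episodes.append(
                        PpsEpisode(person_id=person_id, events=tuple(current))
                    )
                    current = [ev]
                else:
                    unassigned.append(ev)
            prev = ev
        if current:
            episodes.append(PpsEpisode(person_id=person_id, events=tuple(current)))
    return episodes, unassigned


def cleanup(
    episodes: Sequence[PpsEpisode], config: HierarchyConfig
) -> list[PpsEpisode]:
    """Drop over-long episodes, then over-fertile persons.

    An episode is dropped when its recorded length exceeds
    ``max_episode_months`` (month length taken from ``days_per_month``).
    Then, if any sliding 365-day window contains more than
    ``max_episodes_per_year`` of a person's episode starts, *all* of that
    person's episodes are removed.
    """
    max_days = config.max_episode_months * config.days_per_month
    kept = [e for e in episodes if e.recorded_length_days <= max_days]
    by_person: dict[str, list[PpsEpisode]] = {}
    for e in kept:
        by_person.setdefault(e.person_id, []).append(e)
    result: list[PpsEpisode] = []
    for person_id in sorted(by_person):
        eps = sorted(by_person[person_id], key=lambda e: e.first_event_date)
        starts = [e.first_event_date for e in eps]
        excessive = False
        for i, s in enumerate(starts):
            horizon = s + timedelta(days=365)
            count = sum(1 for t in starts[i:] if t < horizon)
            if count > config.max_episodes_per_year:
                excessive = True
                break
        if not excessive:
            result.extend(eps)
    return result


def attach_outcome(
    episode: PpsEpisode,
    outcomes: Sequence[OutcomeEvent],
    next_episode_start: Optional[date],
    config: HierarchyConfig,
) -> PpsEpisode:
    """Attach the highest-priority outcome found in the episode's search window.

    Window: [last event - 14 days, min(next episode start (exclusive),
    last event + (10 - last event's expected minimum month) months)].
    The upper anchor is the last record's date; anchoring at the episode
    start can place the window end before the last record, which would be
    degenerate.  Ties within a category resolve to the earliest date.
    """
    if not episode.events:
        raise ValueError("attach_outcome requires a nonempty episode")
    last = episode.events[-1]
    lo = last.event_date - timedelta(days=14)
    hi = last.event_date + timedelta(
        days=math.floor((10.0 - last.min_month) * config.days_per_month)
    )
    if next_episode_start is not None:
        hi = min(hi, next_episode_start - timedelta(days=1))
    in_window = [
        o
        for o in outcomes
        if o.person_id == episode.person_id and lo <= o.event_date <= hi
    ]
    if not in_window:
        return episode
    best = min(in_window, key=lambda o: (o.category.priority, o.event_date))
    return replace(episode, outcome_category=best.category, outcome_date=best.event_date)


def attach_outcomes(
    episodes: Sequence[PpsEpisode],
    outcomes: Sequence[OutcomeEvent],
    config: HierarchyConfig,
) -> list[PpsEpisode]:
    """Attach outcomes to every episode, threading next-episode starts."""
    by_person: dict[str, list[PpsEpisode]] = {}
    for e in episodes:
        by_person.setdefault(e.person_id, []).append(e)
    result: list[PpsEpisode] = []
    for person_id in sorted(by_person):
        eps = sorted(by_person[person_id], key=lambda e: e.first_event_date)
        for i, ep in enumerate(eps):
            nxt = eps[i + 1].first_event_date if i + 1 < len(eps) else None
            result.append(attach_outcome(ep, outcomes, nxt, config))
    return result
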