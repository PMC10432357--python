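"""Start-date (LMP) estimation from week-level and ranged timing evidence.

Week-level ("Gestation period, X weeks") records back-project to point
start-date candidates; ranged (GR3m) records back-project to plausible
start-date intervals.  Outlier week-level candidates are removed only when
they fall outside *both* the intersection of the ranged intervals and the
Tukey fences (quartiles by linear interpolation, the "type 7" convention)
of the week-level candidates; the surviving evidence yields a point start,
a plausible window, and a precision category.  A deliberately naive
baseline (all week-level candidates, no filtering) is provided for
comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date, timedelta
from typing import Iterable, Optional

import numpy as np

from .concept_registry import ConceptRegistry, TimingUsage
from .ehr_model import ClinicalEvent

__all__ = [
    "GwCandidate",
    "RangedInterval",
    "StartEvidence",
    "StartEstimate",
    "PRECISION_LADDER",
    "collect_evidence",
    "filter_outliers",
    "estimate_start",
    "precision_category",
    "baseline_start",
    "precision_rank",
]

#: Precision categories, finest to coarsest.
PRECISION_LADDER = (
    "week",
    "week_poor-support",
    "two-week",
    "three-week",
    "month",
    "two-months",
    "three-months",
    "non-specific",
)

_RANK = {cat: i for i, cat in enumerate(PRECISION_LADDER)}


def precision_rank(category: str) -> int:
    """Coarseness rank (lower = finer) for dominance comparisons."""
    return _RANK[category]


@dataclass(frozen=True)
class GwCandidate:
    record_date: date
    week: int
    derived_start: date  # record_date - 7 * week


@dataclass(frozen=True)
class RangedInterval:
    record_date: date
    lower: date
    upper: date  # plausible start range [lower, upper]

    def __post_init__(self) -> None:
        assert self.lower <= self.upper


@dataclass(frozen=True)
class StartEvidence:
    gw: tuple[GwCandidate, ...] = ()
    gr3m: tuple[RangedInterval, ...] = ()

    def gr3m_intersection(self) -> Optional[tuple[date, date]]:
        """Intersection of all ranged intervals, or None if empty/absent."""
        if not self.gr3m:
            return None
        lo = max(iv.lower for iv in self.gr3m)
        hi = min(iv.upper for iv in self.gr3m)
        if lo > hi:
            return None
        return lo, hi


@dataclass(frozen=True)
class StartEstimate:
    start_date: Optional[date]
    window: Optional[tuple[date, date]]
    precision_category: str
    n_gw_retained: int
    n_gr3m: int

    @property
    def precision_days(self) -> Optional[int]:
        if self.window is None:
            return None
        return (self.window[1] - self.window[0]).days


def collect_evidence(
    events: Iterable[ClinicalEvent],
    registry: ConceptRegistry,
    days_per_month: Optional[float] = None,
) -> StartEvidence:
    """Build start-date evidence from one episode's events.

    Week-level candidates are deduplicated per record date, keeping the
    maximum week; ranged candidates back-project each GR3m record through
    its expected gestational-month window.
    """
    dpm = days_per_month if days_per_month is not None else registry.hierarchy.days_per_month
    best_per_date: dict[date, int] = {}
    gr3m: list[RangedInterval] = []
    for ev in events:
        week = registry.week_for(ev.concept_id)
        if week is not None:
            prev = best_per_date.get(ev.event_date)
            if prev is None or week > prev:
                best_per_date[ev.event_date] = week
            continue
        tc = registry.timing.get(ev.concept_id)
        if tc is not None and tc.usage is TimingUsage.GR3M:
            gr3m.append(
                RangedInterval(
                    record_date=ev.event_date,
                    lower=ev.event_date - timedelta(days=math.floor(tc.max_month * dpm)),
                    upper=ev.event_date - timedelta(days=math.ceil(tc.min_month * dpm)),
                )
            )
    gw = tuple(
        GwCandidate(record_date=d, week=w, derived_start=d - timedelta(days=7 * w))
        for d, w in sorted(best_per_date.items())
    )
    return StartEvidence(gw=gw, gr3m=tuple(sorted(gr3m, key=lambda iv: iv.record_date)))


def _tukey_fences(starts: list[date]) -> tuple[float, float]:
    ords = np.array([d.toordinal() for d in starts], dtype=float)
    q1, q3 = np.percentile(ords, [25.0, 75.0])  # linear interpolation (type 7)
    iqr = q3 - q1
    return q1 - 1.5 * iqr, q3 + 1.5 * iqr


def filter_outliers(
    evidence: StartEvidence, disjunctive: bool = False
) -> StartEvidence:
    """Remove outlier week-level candidates.

    Default (conjunctive) reading: a candidate is removed only when it lies
    outside the intersection of the ranged start intervals (when that
    intersection is nonempty) AND outside the Tukey fences of the week-level
    candidates.  With no usable ranged evidence only the fence condition
    applies; with fewer than three week-level candidates the fence condition
    never removes.  ``disjunctive=True`` switches to the either-condition
    reading for sensitivity analysis.
    """
    if not evidence.gw:
        return evidence
    intersection = evidence.gr3m_intersection()
    n = len(evidence.gw)
    fences = _tukey_fences([c.derived_start for c in evidence.gw]) if n >= 3 else None

    retained = []
    for cand in evidence.gw:
        outside_gr = True
        if intersection is not None:
            outside_gr = not (intersection[0] <= cand.derived_start <= intersection[1])
        outside_iqr = False
        if fences is not None:
            o = cand.derived_start.toordinal()
            outside_iqr = o < fences[0] or o > fences[1]
        if intersection is None:
            removed = outside_iqr if not disjunctive else outside_iqr
        elif disjunctive:
            removed = outside_gr or outside_iqr
        else:
            removed = outside_gr and outside_iqr
        if not removed:
            retained.append(cand)
    if not retained:
        # Degenerate: every candidate rejected; fall back to keeping all
        # rather than discarding the episode's only point evidence.
        return evidence
    return StartEvidence(gw=tuple(retained), gr3m=evidence.gr3m)


def precision_category(window_days: Optional[int], n_gw: int) -> str:
    """Map a plausible-window width (days) and GW support count to a category."""
    if window_days is None:
        return "non-specific"
    if window_days < 0:
        raise ValueError("window_days must be non-negative")
    if n_gw == 1:
        return "week_poor-support"
    if window_days <= 7:
        return "week"
    if window_days <= 14:
        return "two-week"
    if window_days <= 21:
        return "three-week"
    if window_days <= 28:
        return "month"
    if window_days <= 56:
        return "two-months"
    if window_days <= 84:
        return "three-months"
    return "non-specific"


def estimate_start(filtered: StartEvidence) -> StartEstimate:
    """Point start, window, and precision from (filtered) evidence.

    The retained week-level candidate with the latest record date supplies
    the point start (late-pregnancy week records are empirically the most
    precise).  The window spans the retained week-level starts when two or
    more remain, else the ranged-interval intersection when only ranged
    evidence exists.
    """
    n_gw = len(filtered.gw)
    n_gr3m = len(filtered.gr3m)
    if n_gw:
        latest = max(filtered.gw, key=lambda c: c.record_date)
        starts = [c.derived_start for c in filtered.gw]
        window = (min(starts), max(starts)) if n_gw >= 2 else (starts[0], starts[0])
        width = (window[1] - window[0]).days
        return StartEstimate(
            start_date=latest.derived_start,
            window=window,
            precision_category=precision_category(width, n_gw),
            n_gw_retained=n_gw,
            n_gr3m=n_gr3m,
        )
    intersection = filtered.gr3m_intersection()
    if intersection is not None:
        width = (intersection[1] - intersection[0]).days
        return StartEstimate(
            start_date=None,
            window=intersection,
            precision_category=precision_category(width, 0),
            n_gw_retained=0,
            n_gr3m=n_gr3m,
        )
    return StartEstimate(
        start_date=None,
        window=None,
        precision_category="non-specific",
        n_gw_retained=0,
        n_gr3m=n_gr3m,
    )


def baseline_start(evidence: StartEvidence) -> StartEstimate:
    """Comparator: all week-level candidates, no outlier removal, no ranged
    evidence; window is the maximum pairwise start-date difference."""
    return estimate_start(StartEvidence(gw=evidence.gw, gr3m=()))
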