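"""Fusion of the two episode streams into final flagged, scored episodes.

Per person, overlapping rule-based (HIP) and progression-based (PPS)
episodes are paired greedily by closest end dates — resolving any episode
that overlaps more than two others — and each surviving pair is merged to
the union of its two intervals with both detection flags set.  Outcome
concordance between the two algorithms, together with the plausibility of
the estimated gestational age at the outcome, yields a 0-2 score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Optional, Sequence

from .concept_registry import HierarchyConfig, OutcomeCategory
from .hip import HipEpisode
from .pps import PpsEpisode

__all__ = [
    "MergedEpisode",
    "HippsEpisode",
    "resolve_overlaps",
    "concordance",
]


@dataclass(frozen=True)
class MergedEpisode:
    """An interval produced by overlap resolution, before scoring/ESD."""

    person_id: str
    start_date: date
    end_date: date
    hip: Optional[HipEpisode] = None
    pps: Optional[PpsEpisode] = None

    @property
    def hip_flag(self) -> bool:
        return self.hip is not None

    @property
    def pps_flag(self) -> bool:
        return self.pps is not None


@dataclass
class HippsEpisode:
    """Final episode with provenance flags, score, and start precision."""

    person_id: str
    episode_id: str
    start_date: date
    end_date: date
    hip_flag: bool = False
    pps_flag: bool = False
    outcome_category: Optional[OutcomeCategory] = None
    outcome_date: Optional[date] = None
    concordance_score: Optional[int] = None
    max_week: Optional[int] = None
    inferred_start_date: Optional[date] = None
    recorded_start_date: Optional[date] = None
    precision_category: Optional[str] = None
    precision_days: Optional[int] = None
    window: Optional[tuple[date, date]] = None
    basis: str = ""

    @property
    def recorded_length_days(self) -> Optional[int]:
        if self.recorded_start_date is None or self.end_date is None:
            return None
        return (self.end_date - self.recorded_start_date).days

    @property
    def inferred_length_days(self) -> Optional[int]:
        """Outcome date minus inferred start (LMP), when both exist."""
        if self.inferred_start_date is None or self.outcome_date is None:
            return None
        return (self.outcome_date - self.inferred_start_date).days


def _interval(ep) -> tuple[date, date]:
    if isinstance(ep, HipEpisode):
        return ep.start_date, ep.end_date
    return ep.first_event_date, ep.end_date


def _overlap(a: tuple[date, date], b: tuple[date, date]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def resolve_overlaps(
    hip_eps: Sequence[HipEpisode], pps_eps: Sequence[PpsEpisode]
) -> list[MergedEpisode]:
    """Pair overlapping episodes across the two streams and merge each pair.

    The bipartite overlap graph is resolved greedily in ascending
    |end - end| (ties: earlier start, then input order), so an episode
    overlapping more than two others keeps only its closest-end pairing.
    Merged pairs span [min(starts), max(ends)]; unpaired episodes pass
    through with a single flag.
    """
    merged: list[MergedEpisode] = []
    persons = sorted(
        {e.person_id for e in hip_eps} | {e.person_id for e in pps_eps}
    )
    hips_by_person: dict[str, list[HipEpisode]] = {}
    for h in hip_eps:
        hips_by_person.setdefault(h.person_id, []).append(h)
    pps_by_person: dict[str, list[PpsEpisode]] = {}
    for p in pps_eps:
        pps_by_person.setdefault(p.person_id, []).append(p)

    for person_id in persons:
        hips = sorted(hips_by_person.get(person_id, []), key=lambda e: _interval(e))
        pps = sorted(pps_by_person.get(person_id, []), key=lambda e: _interval(e))
        pairs = []
        for i, h in enumerate(hips):
            hi = _interval(h)
            for j, p in enumerate(pps):
                pi = _interval(p)
                if _overlap(hi, pi):
                    end_gap = abs((hi[1] - pi[1]).days)
                    pairs.append((end_gap, min(hi[0], pi[0]), i, j))
        pairs.sort()
        used_h: set[int] = set()
        used_p: set[int] = set()
        person_merged: list[MergedEpisode] = []
        for _, _, i, j in pairs:
            if i in used_h or j in used_p:
                continue
            used_h.add(i)
            used_p.add(j)
            hi, pi = _interval(hips[i]), _interval(pps[j])
            person_merged.append(
                MergedEpisode(
                    person_id=person_id,
                    start_date=min(hi[0], pi[0]),
                    end_date=max(hi[1], pi[1]),
                    hip=hips[i],
                    pps=pps[j],
                )
            )
        for i, h in enumerate(hips):
            if i not in used_h:
                s, e = _interval(h)
                person_merged.append(
                    MergedEpisode(person_id=person_id, start_date=s, end_date=e, hip=h)
                )
        for j, p in enumerate(pps):
            if j not in used_p:
                s, e = _interval(p)
                person_merged.append(
                    MergedEpisode(person_id=person_id, start_date=s, end_date=e, pps=p)
                )
        person_merged.sort(key=lambda m: (m.start_date, m.end_date))
        merged.extend(_truncate_residual_overlaps(person_merged))
    return merged


def _truncate_residual_overlaps(eps: list[MergedEpisode]) -> list[MergedEpisode]:
    """Clip residual per-person overlaps left by unpaired pass-throughs.

    A pair-union can swallow a neighbouring unpaired episode's back-projected
    start; the later episode's start is clipped to the day after the earlier
    ends (episodes fully contained are dropped), guaranteeing the final
    non-overlap invariant.
    """
    result: list[MergedEpisode] = []
    for ep in eps:
        if result and ep.start_date <= result[-1].end_date:
            new_start = result[-1].end_date + timedelta(days=1)
            if new_start >= ep.end_date:
                continue
            ep = MergedEpisode(
                person_id=ep.person_id,
                start_date=new_start,
                end_date=ep.end_date,
                hip=ep.hip,
                pps=ep.pps,
            )
        result.append(ep)
    return result


def concordance(
    hip_outcome: Optional[tuple[OutcomeCategory, date]],
    pps_outcome: Optional[tuple[OutcomeCategory, date]],
    inferred_ga_at_outcome_days: Optional[int],
    config: HierarchyConfig,
) -> tuple[Optional[OutcomeCategory], Optional[date], Optional[int]]:
    """Resolve the final outcome and assign the 0-2 concordance score.

    Score 2: categories match, outcome dates within 14 days, and estimated
    gestational age at the outcome lies inside the category's term window.
    Score 1: gestational age in window but no cross-algorithm match
    (including single-sided outcomes).  Score 0: gestational age outside
    the window, even with a match.  Mismatched outcomes keep the later one.
    """
    if hip_outcome is None and pps_outcome is None:
        return None, None, None
    if hip_outcome is not None and pps_outcome is not None:
        (h_cat, h_date), (p_cat, p_date) = hip_outcome, pps_outcome
        matched = (
            h_cat is p_cat
            and abs((h_date - p_date).days) <= config.outcome_match_window_days
        )
        if matched:
            final_cat, final_date = h_cat, h_date
        else:
            final_cat, final_date = (h_cat, h_date) if h_date >= p_date else (p_cat, p_date)
    else:
        matched = False
        final_cat, final_date = hip_outcome or pps_outcome  # type: ignore[misc]
    lo, hi = config.term_window(final_cat)
    in_window = (
        inferred_ga_at_outcome_days is not None
        and lo < inferred_ga_at_outcome_days <= hi
    )
    if not in_window:
        score = 0
    elif matched:
        score = 2
    else:
        score = 1
    return final_cat, final_date, score
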