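from __future__ import annotations

from datetime import date, timedelta

import numpy as np
import pytest

from hipps.concept_registry import HierarchyConfig, OutcomeCategory
from hipps.hip import OutcomeEvent
from hipps.pps import (
    PpsEpisode,
    ProgressionEvent,
    attach_outcome,
    attach_outcomes,
    build_progressions,
    cleanup,
    pair_compatible,
)

from .conftest import day

CONFIG = HierarchyConfig()
DPM = CONFIG.days_per_month


def pe(offset: int, lo: float, hi: float, person="A", cid=0) -> ProgressionEvent:
    return ProgressionEvent(
        person_id=person,
        event_date=day(offset),
        concept_id=cid,
        min_month=lo,
        max_month=hi,
    )


class TestPairCompatible:
    def test_estriol_to_late_concept_75_days(self):
        a = pe(0, 3.75, 5.5)
        b = pe(75, 6.0, 7.0)
        # allowed window [0.5, 3.25] months = [15.2, 98.9] days
        assert pair_compatible(a, b, DPM)

    def test_same_pair_150_days_false(self):
        assert not pair_compatible(pe(0, 3.75, 5.5), pe(150, 6.0, 7.0), DPM)

    def test_degenerate_same_concept_zero_gap(self):
        assert pair_compatible(pe(0, 6.0, 7.0), pe(0, 6.0, 7.0), DPM)

    def test_lower_bound_enforced(self):
        # gap 10 days < 15.2-day minimum
        assert not pair_compatible(pe(0, 3.75, 5.5), pe(10, 6.0, 7.0), DPM)

    def test_misordered_dates_rejected(self):
        with pytest.raises(ValueError):
            pair_compatible(pe(10, 1, 2), pe(0, 1, 2), DPM)


class TestBuildProgressions:
    def test_single_pregnancy_three_events(self):
        events = [pe(45, 1.0, 2.0), pe(150, 5.0, 6.0), pe(250, 8.0, 9.0)]
        episodes, noise = build_progressions(events, CONFIG)
        assert len(episodes) == 1 and not noise
        assert len(episodes[0].events) == 3

    def test_incompatible_event_with_70_day_gap_starts_new_episode(self):
        events = [pe(0, 8.0, 9.0), pe(70, 1.0, 2.0)]
        episodes, noise = build_progressions(events, CONFIG)
        assert len(episodes) == 2 and not noise

    def test_incompatible_event_with_30_day_gap_is_unassigned(self):
        events = [pe(0, 8.0, 9.0), pe(30, 1.0, 2.0)]
        episodes, noise = build_progressions(events, CONFIG)
        assert len(episodes) == 1
        assert [e.event_date for e in noise] == [day(30)]

    def test_unassigned_event_can_anchor_successive_pair(self):
        # Third event incompatible with the episode but compatible with the
        # noise event immediately before it -> extends the episode.
        events = [pe(0, 8.0, 9.0), pe(30, 1.0, 2.0), pe(45, 1.0, 2.0)]
        episodes, noise = build_progressions(events, CONFIG)
        assert len(episodes) == 1
        assert len(episodes[0].events) == 2
        assert len(noise) == 1


class TestCleanup:
    def _episode(self, offsets, person="A"):
        return PpsEpisode(
            person_id=person,
            events=tuple(pe(o, 1.0, 2.0, person=person) for o in offsets),
        )

    def test_episode_over_12_months_dropped(self):
        eps = [self._episode([0, 400]), self._episode([500, 600])]
        kept = cleanup(eps, CONFIG)
        assert len(kept) == 1 and kept[0].first_event_date == day(500)

    def test_six_starts_in_a_year_drops_all_person_episodes(self):
        eps = [self._episode([i * 50, i * 50 + 10]) for i in range(6)]
        eps.append(self._episode([0, 10], person="B"))
        kept = cleanup(eps, CONFIG)
        assert {e.person_id for e in kept} == {"B"}

    def test_two_episodes_eight_months_apart_retained(self):
        eps = [self._episode([0, 30]), self._episode([244, 280])]
        assert len(cleanup(eps, CONFIG)) == 2

    def test_five_starts_in_a_year_retained(self):
        eps = [self._episode([i * 70, i * 70 + 10]) for i in range(5)]
        assert len(cleanup(eps, CONFIG)) == 5


class TestAttachOutcome:
    def _episode(self, offsets_with_windows):
        return PpsEpisode(
            person_id="A",
            events=tuple(pe(o, lo, hi) for o, lo, hi in offsets_with_windows),
        )

    def test_outcome_shortly_after_end_attached(self):
        ep = self._episode([(0, 1.0, 2.0), (250, 8.0, 9.0)])
        out = OutcomeEvent("A", day(253), OutcomeCategory.LIVE_BIRTH)
        attached = attach_outcome(ep, [out], None, CONFIG)
        assert attached.outcome_category is OutcomeCategory.LIVE_BIRTH
        assert attached.outcome_date == day(253)

    def test_window_end_is_ten_months_minus_min_month_after_last_record(self):
        ep = self._episode([(250, 8.0, 9.0)])
        limit = 250 + int(np.floor((10 - 8.0) * DPM))  # 60 days past last record
        ok = OutcomeEvent("A", day(limit), OutcomeCategory.LIVE_BIRTH)
        too_late = OutcomeEvent("A", day(limit + 1), OutcomeCategory.LIVE_BIRTH)
        assert attach_outcome(ep, [ok], None, CONFIG).outcome_category is not None
        assert attach_outcome(ep, [too_late], None, CONFIG).outcome_category is None

    def test_hierarchy_selects_live_birth_over_abortion(self):
        ep = self._episode([(0, 1.0, 2.0), (250, 8.0, 9.0)])
        outs = [
            OutcomeEvent("A", day(252), OutcomeCategory.INDUCED_ABORTION),
            OutcomeEvent("A", day(255), OutcomeCategory.LIVE_BIRTH),
        ]
        attached = attach_outcome(ep, outs, None, CONFIG)
        assert attached.outcome_category is OutcomeCategory.LIVE_BIRTH

    def test_outcome_20_days_before_end_not_attached(self):
        ep = self._episode([(0, 1.0, 2.0), (250, 8.0, 9.0)])
        out = OutcomeEvent("A", day(230), OutcomeCategory.LIVE_BIRTH)
        assert attach_outcome(ep, [out], None, CONFIG).outcome_category is None

    def test_next_episode_start_caps_window_exclusively(self):
        ep = self._episode([(250, 8.0, 9.0)])
        out = OutcomeEvent("A", day(260), OutcomeCategory.LIVE_BIRTH)
        assert (
            attach_outcome(ep, [out], day(260), CONFIG).outcome_category is None
        )
        assert (
            attach_outcome(ep, [out], day(261), CONFIG).outcome_category is not None
        )


# ---------------------------------------------------------------------------
# Exhaustive segmentation oracle
# ---------------------------------------------------------------------------


def _oracle_compatible(a: ProgressionEvent, b: ProgressionEvent, dpm: float) -> bool:
    # Independent re-statement of the timing predicate.
    delta = (b.event_date - a.event_date).days
    if delta < 0:
        return False
    lo = (b.min_month - a.max_month) * dpm
    hi = (b.max_month - a.min_month) * dpm
    return max(0.0, lo) <= delta <= hi


def oracle_segmentations(events, config):
    """All fate assignments (extend / new episode / noise) consistent with the
    compatibility and retry predicates, by exhaustive depth-first search."""
    dpm = config.days_per_month
    results = []

    def episode_members(fates):
        episodes, current = [], []
        for ev, fate in zip(events, fates):
            if fate == "new":
                if current:
                    episodes.append(current)
                current = [ev]
            elif fate == "extend":
                current.append(ev)
        if current:
            episodes.append(current)
        return episodes, current

    def rec(i, fates):
        if i == len(events):
            results.append(tuple(fates))
            return
        ev = events[i]
        if i == 0:
            rec(1, ["new"])
            return
        prev = events[i - 1]
        _, current = episode_members(fates)
        candidates = list(current)
        if prev not in candidates:
            candidates.append(prev)
        compat = any(_oracle_compatible(c, ev, dpm) for c in candidates)
        gap = (ev.event_date - prev.event_date).days
        for fate in ("extend", "new", "noise"):
            if fate == "extend":
                ok = compat
            elif fate == "new":
                ok = not compat and gap >= config.retry_days
            else:
                ok = not compat and gap < config.retry_days
            if ok:
                rec(i + 1, fates + [fate])

    rec(0, [])
    return results


def oracle_episodes(events, config):
    segmentations = oracle_segmentations(events, config)
    assert len(segmentations) == 1, "scan semantics must be deterministic"
    fates = segmentations[0]
    episodes, current = [], []
    for ev, fate in zip(events, fates):
        if fate == "new":
            if current:
                episodes.append(tuple(current))
            current = [ev]
        elif fate == "extend":
            current.append(ev)
    if current:
        episodes.append(tuple(current))
    return episodes


def random_instance(rng: np.random.Generator, n_events: int) -> list[ProgressionEvent]:
    events = []
    offset = 0
    for i in range(n_events):
        offset += int(rng.integers(0, 120))
        lo = float(rng.uniform(0.3, 8.0))
        hi = min(10.0, lo + float(rng.uniform(0.25, 2.9)))
        events.append(pe(offset, round(lo, 2), round(hi, 2), cid=i))
    return events


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_scan_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(50):
            n = int(rng.integers(1, 9))
            events = random_instance(rng, n)
            episodes, _ = build_progressions(events, CONFIG)
            got = [ep.events for ep in episodes]
            assert got == oracle_episodes(events, CONFIG)


class TestInvariantsOnSimulation:
    def test_pps_episode_count_matches_truth_and_supports_hip(self, clean_run, registry):
        sim, result = clean_run
        truth_counts: dict[str, int] = {}
        for t in sim.truth:
            truth_counts[t.person_id] = truth_counts.get(t.person_id, 0) + 1
        pps_counts: dict[str, int] = {}
        for ep in result.pps_episodes:
            pps_counts[ep.person_id] = pps_counts.get(ep.person_id, 0) + 1
        assert pps_counts == truth_counts
        # Every rule-based episode with an outcome is overlapped by a
        # progression episode (the support notion).
        pps_by_person: dict[str, list[PpsEpisode]] = {}
        for ep in result.pps_episodes:
            pps_by_person.setdefault(ep.person_id, []).append(ep)
        for h in result.hip_episodes:
            if h.outcome_category is None:
                continue
            assert any(
                p.first_event_date <= h.end_date and h.start_date <= p.end_date
                for p in pps_by_person.get(h.person_id, [])
            )

    def test_no_overlap_and_retry_gap(self, clean_run, hconfig):
        _, result = clean_run
        by_person: dict[str, list[PpsEpisode]] = {}
        for ep in result.pps_episodes:
            by_person.setdefault(ep.person_id, []).append(ep)
        for eps in by_person.values():
            eps = sorted(eps, key=lambda e: e.first_event_date)
            for a, b in zip(eps, eps[1:]):
                assert a.last_event_date < b.first_event_date
                assert (b.first_event_date - a.last_event_date).days >= hconfig.retry_days
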