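from __future__ import annotations

from datetime import date, timedelta

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hipps.concept_registry import GW_CONCEPT_BASE
from hipps.esd import (
    GwCandidate,
    RangedInterval,
    StartEvidence,
    baseline_start,
    collect_evidence,
    estimate_start,
    filter_outliers,
    precision_category,
    precision_rank,
)

from .conftest import day, mk_event


def gw(derived_offset: int, week: int = 12) -> GwCandidate:
    start = day(derived_offset)
    return GwCandidate(
        record_date=start + timedelta(days=7 * week), week=week, derived_start=start
    )


def interval(lo: int, hi: int, record_offset: int = 200) -> RangedInterval:
    return RangedInterval(record_date=day(record_offset), lower=day(lo), upper=day(hi))


class TestCollectEvidence:
    def test_same_date_keeps_max_week(self, registry):
        d = day(84)
        events = [
            mk_event("A", d, GW_CONCEPT_BASE + 12),
            mk_event("A", d, GW_CONCEPT_BASE + 14),
        ]
        ev = collect_evidence(events, registry)
        assert len(ev.gw) == 1 and ev.gw[0].week == 14

    def test_estriol_interval_back_projection(self, registry):
        d = day(150)
        ev = collect_evidence([mk_event("A", d, 4220001, domain="measurement")], registry)
        (iv,) = ev.gr3m
        # floor(5.5 * 30.44) = 167, ceil(3.75 * 30.44) = 115
        assert iv.lower == d - timedelta(days=167)
        assert iv.upper == d - timedelta(days=115)

    def test_no_evidence(self, registry):
        ev = collect_evidence([mk_event("A", day(0), 999999)], registry)
        assert ev.gw == () and ev.gr3m == ()


class TestFilterOutliers:
    def test_outlier_outside_both_conditions_removed(self):
        evidence = StartEvidence(
            gw=(gw(0), gw(2), gw(3), gw(40)),
            gr3m=(interval(-5, 10),),
        )
        filtered = filter_outliers(evidence)
        assert [c.derived_start for c in filtered.gw] == [day(0), day(2), day(3)]

    def test_two_candidates_never_removed(self):
        evidence = StartEvidence(gw=(gw(0), gw(3)))
        assert filter_outliers(evidence) == evidence

    def test_all_inside_intersection_kept(self):
        evidence = StartEvidence(
            gw=(gw(0), gw(2), gw(3), gw(40)),
            gr3m=(interval(-5, 45),),
        )
        # day(40) is inside the ranged intersection, so the conjunctive rule
        # keeps it even though it violates the fences.
        assert filter_outliers(evidence) == evidence

    def test_disjunctive_mode_removes_on_either_condition(self):
        evidence = StartEvidence(
            gw=(gw(0), gw(2), gw(3), gw(40)),
            gr3m=(interval(-5, 45),),
        )
        filtered = filter_outliers(evidence, disjunctive=True)
        assert [c.derived_start for c in filtered.gw] == [day(0), day(2), day(3)]

    def test_no_gr3m_iqr_only(self):
        evidence = StartEvidence(gw=(gw(0), gw(1), gw(2), gw(60)))
        filtered = filter_outliers(evidence)
        assert [c.derived_start for c in filtered.gw] == [day(0), day(1), day(2)]

    def test_conflicting_gr3m_intersection_discarded(self):
        # Disjoint ranged intervals -> empty intersection -> fences only.
        evidence = StartEvidence(
            gw=(gw(0), gw(1), gw(2), gw(60)),
            gr3m=(interval(-10, 5), interval(50, 70)),
        )
        filtered = filter_outliers(evidence)
        assert [c.derived_start for c in filtered.gw] == [day(0), day(1), day(2)]

    @given(
        st.lists(st.integers(min_value=-300, max_value=300), min_size=1, max_size=12)
    )
    @settings(max_examples=150, deadline=None)
    def test_retained_subset_and_window_shrinks(self, offsets):
        evidence = StartEvidence(gw=tuple(gw(o, week=10) for o in sorted(set(offsets))))
        filtered = filter_outliers(evidence)
        assert set(filtered.gw) <= set(evidence.gw)
        assert len(filtered.gw) >= 1
        if len(filtered.gw) >= 2 and len(evidence.gw) >= 2:
            span = lambda ev: (
                max(c.derived_start for c in ev.gw)
                - min(c.derived_start for c in ev.gw)
            ).days
            assert span(filtered) <= span(evidence)


class TestEstimateStart:
    def test_week_category_start_from_latest_record(self):
        # Latest record date wins even when it implies a different start.
        cands = (gw(0, week=8), gw(2, week=20), gw(4, week=30))
        est = estimate_start(StartEvidence(gw=cands))
        assert est.precision_category == "week"
        assert est.start_date == day(4)
        assert est.window == (day(0), day(4))

    def test_single_gw_is_week_poor_support(self):
        est = estimate_start(StartEvidence(gw=(gw(0),)))
        assert est.precision_category == "week_poor-support"
        assert est.start_date == day(0)
        assert est.precision_days == 0

    def test_gr3m_only_wide_window(self):
        est = estimate_start(StartEvidence(gr3m=(interval(0, 70),)))
        assert est.start_date is None
        assert est.window == (day(0), day(70))
        assert est.precision_category == "three-months"

    def test_no_evidence_non_specific(self):
        est = estimate_start(StartEvidence())
        assert est.precision_category == "non-specific"
        assert est.window is None and est.start_date is None


class TestPrecisionCategory:
    @pytest.mark.parametrize(
        "days,n_gw,expected",
        [
            (None, 0, "non-specific"),
            (0, 1, "week_poor-support"),
            (10, 1, "week_poor-support"),
            (0, 2, "week"),
            (7, 3, "week"),
            (8, 2, "two-week"),
            (10, 3, "two-week"),
            (14, 2, "two-week"),
            (15, 2, "three-week"),
            (21, 2, "three-week"),
            (22, 2, "month"),
            (28, 2, "month"),
            (29, 2, "two-months"),
            (56, 2, "two-months"),
            (57, 2, "three-months"),
            (60, 2, "three-months"),
            (84, 2, "three-months"),
            (85, 2, "non-specific"),
        ],
    )
    def test_ladder(self, days, n_gw, expected):
        assert precision_category(days, n_gw) == expected

    def test_negative_window_rejected(self):
        with pytest.raises(ValueError):
            precision_category(-1, 2)

    def test_rank_orders_ladder(self):
        assert precision_rank("week") < precision_rank("two-week")
        assert precision_rank("three-months") < precision_rank("non-specific")


class TestBaseline:
    def test_baseline_window_is_max_pairwise_difference(self):
        evidence = StartEvidence(gw=(gw(0), gw(2), gw(40)))
        est = baseline_start(evidence)
        assert est.precision_days == 40
        assert est.precision_category == "two-months"

    def test_contrast_with_filtered_estimate(self):
        evidence = StartEvidence(
            gw=(gw(0), gw(1), gw(2), gw(40)), gr3m=(interval(-5, 10),)
        )
        filtered = estimate_start(filter_outliers(evidence))
        base = baseline_start(evidence)
        assert filtered.precision_category == "week"
        assert base.precision_category == "two-months"

    def test_no_gw_non_specific(self):
        est = baseline_start(StartEvidence(gr3m=(interval(0, 20),)))
        assert est.precision_category == "non-specific"


class TestDominanceOnSimulation:
    def test_esd_never_coarser_than_baseline(self, clean_run):
        _, result = clean_run
        for ep in result.episodes:
            esd = result.esd_estimates[ep.episode_id]
            base = result.baseline_estimates[ep.episode_id]
            assert precision_rank(esd.precision_category) <= precision_rank(
                base.precision_category
            )

    def test_noise_free_recovery_exact(self, clean_run):
        sim, result = clean_run
        lmp_by_person = {}
        for t in sim.truth:
            lmp_by_person.setdefault(t.person_id, []).append(t.true_lmp)
        for ep in result.episodes:
            est = result.esd_estimates[ep.episode_id]
            if est.n_gw_retained >= 2:
                assert est.precision_category == "week"
                assert est.start_date in lmp_by_person[ep.person_id]
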