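from __future__ import annotations

from datetime import timedelta

import numpy as np
import pytest

from hipps.concept_registry import OutcomeCategory, TimingUsage
from hipps.synth_cohort import (
    SimConfig,
    SimConfigError,
    _LENGTH_PARAMS,
    _draw_length,
    corrupt_events,
    simulate_cohort,
)

LB = OutcomeCategory.LIVE_BIRTH


class TestSimConfigValidation:
    def test_probability_vector_must_sum_to_one(self):
        with pytest.raises(SimConfigError, match="sum"):
            SimConfig(random_seed=1, outcome_mix={LB: 0.5})

    def test_noise_probability_bounds(self):
        with pytest.raises(SimConfigError):
            SimConfig(random_seed=1, p_missing_gw=1.5)

    def test_seed_is_mandatory(self):
        with pytest.raises(TypeError):
            SimConfig()  # type: ignore[call-arg]

    def test_jitter_capped_at_3_days(self):
        with pytest.raises(SimConfigError):
            SimConfig(random_seed=1, gw_jitter_days=4)

    def test_infeasible_gap_rejected(self):
        with pytest.raises(SimConfigError, match="gap"):
            SimConfig(random_seed=1, inter_pregnancy_gap_days=(30, 100))


class TestSimulateCohort:
    def test_seeded_determinism(self, registry):
        cfg = SimConfig(random_seed=7, n_persons=50)
        r1 = simulate_cohort(cfg, registry)
        r2 = simulate_cohort(cfg, registry)
        assert r1.persons == r2.persons
        assert r1.events == r2.events
        assert r1.truth == r2.truth

    def test_different_seeds_differ(self, registry):
        r1 = simulate_cohort(SimConfig(random_seed=1, n_persons=20), registry)
        r2 = simulate_cohort(SimConfig(random_seed=2, n_persons=20), registry)
        assert r1.events != r2.events

    def test_degenerate_mix_all_live_birth(self, registry):
        mix = {LB: 1.0}
        cfg = SimConfig(random_seed=3, n_persons=100, outcome_mix=mix)
        result = simulate_cohort(cfg, registry)
        assert all(t.outcome_category is LB for t in result.truth)

    def test_missing_outcome_suppresses_events_not_truth(self, registry):
        cfg = SimConfig(random_seed=4, n_persons=50, p_missing_outcome=1.0)
        result = simulate_cohort(cfg, registry)
        outcome_ids = set(registry.outcomes)
        assert not any(e.concept_id in outcome_ids for e in result.events)
        assert any(t.outcome_category is not None for t in result.truth)

    def test_truth_outcome_date_consistency(self, registry):
        result = simulate_cohort(SimConfig(random_seed=5, n_persons=50), registry)
        for t in result.truth:
            if t.outcome_category is not None:
                assert t.outcome_date == t.true_lmp + timedelta(
                    days=t.gestational_length_days
                )

    def test_gw_events_back_project_exactly_to_lmp(self, registry):
        # Truth-recoverability: with zero noise every GW record determines
        # the true LMP exactly.
        result = simulate_cohort(SimConfig(random_seed=6, n_persons=40), registry)
        truth_by_person = {}
        for t in result.truth:
            truth_by_person.setdefault(t.person_id, []).append(t.true_lmp)
        n_checked = 0
        for ev in result.events:
            week = registry.week_for(ev.concept_id)
            if week is None:
                continue
            derived = ev.event_date - timedelta(days=7 * week)
            assert derived in truth_by_person[ev.person_id]
            n_checked += 1
        assert n_checked > 50

    def test_timed_events_fall_inside_expected_windows(self, registry):
        result = simulate_cohort(SimConfig(random_seed=8, n_persons=40), registry)
        truth_by_person = {}
        for t in result.truth:
            truth_by_person.setdefault(t.person_id, []).append(t)
        dpm = registry.hierarchy.days_per_month
        for ev in result.events:
            tc = registry.timing.get(ev.concept_id)
            if tc is None:
                continue
            offsets = [
                (ev.event_date - t.true_lmp).days
                for t in truth_by_person[ev.person_id]
            ]
            offset = min((o for o in offsets if o >= 0), default=None)
            assert offset is not None
            assert tc.min_month * dpm <= offset + 1  # integer day rounding
            assert offset <= tc.max_month * dpm

    def test_gestational_lengths_within_term_windows(self, registry, hconfig):
        rng = np.random.default_rng(0)
        for category, (_, _, lo, hi) in _LENGTH_PARAMS.items():
            draws = [_draw_length(rng, category) for _ in range(10_000 // 7)]
            assert all(lo <= d <= hi for d in draws)
            if category is not None:
                t_lo, t_hi = hconfig.term_window(category)
                assert all(t_lo < d <= t_hi for d in draws)

    def test_registry_missing_roles_rejected(self, registry):
        from hipps.concept_registry import ConceptRegistry

        bare = ConceptRegistry(
            outcomes=dict(registry.outcomes),
            gestation_weeks=dict(registry.gestation_weeks),
            timing={},
        )
        with pytest.raises(SimConfigError):
            simulate_cohort(SimConfig(random_seed=1, n_persons=5), bare)


class TestCorruptEvents:
    def test_no_noise_is_identity(self, registry, clean_sim):
        cfg, result = clean_sim
        assert corrupt_events(result.events, cfg, registry) == result.events

    def test_full_gw_dropout(self, registry, clean_sim):
        cfg, result = clean_sim
        noisy_cfg = SimConfig(random_seed=cfg.random_seed, n_persons=cfg.n_persons, p_missing_gw=1.0)
        corrupted = corrupt_events(result.events, noisy_cfg, registry)
        assert not any(registry.week_for(e.concept_id) for e in corrupted)
        # non-GW events untouched
        n_other = sum(1 for e in result.events if registry.week_for(e.concept_id) is None)
        assert len(corrupted) == n_other

    def test_original_table_untouched(self, registry, clean_sim):
        cfg, result = clean_sim
        noisy_cfg = SimConfig(random_seed=1, n_persons=cfg.n_persons, p_missing_gw=0.5)
        before = tuple(result.events)
        corrupt_events(result.events, noisy_cfg, registry)
        assert tuple(result.events) == before

    def test_injected_outliers_deviate_over_28_days(self, registry, clean_sim):
        cfg, result = clean_sim
        noisy_cfg = SimConfig(
            random_seed=cfg.random_seed, n_persons=cfg.n_persons, p_outlier_gw=0.2
        )
        corrupted = corrupt_events(result.events, noisy_cfg, registry)
        inserted = set(corrupted.events) - set(result.events)
        assert inserted
        truth_by_person = {}
        for t in result.truth:
            truth_by_person.setdefault(t.person_id, []).append(t.true_lmp)
        for ev in inserted:
            week = registry.week_for(ev.concept_id)
            assert week is not None
            derived = ev.event_date - timedelta(days=7 * week)
            deviation = min(
                abs((derived - lmp).days) for lmp in truth_by_person[ev.person_id]
            )
            assert deviation > 28

    def test_historical_records_outside_pregnancies(self, registry, clean_sim):
        cfg, result = clean_sim
        noisy_cfg = SimConfig(
            random_seed=cfg.random_seed, n_persons=cfg.n_persons, p_historical=1.0
        )
        corrupted = corrupt_events(result.events, noisy_cfg, registry)
        inserted = sorted(set(corrupted.events) - set(result.events))
        assert inserted
        truth_by_person = {}
        for t in result.truth:
            truth_by_person.setdefault(t.person_id, []).append(t)
        for ev in inserted:
            for t in truth_by_person[ev.person_id]:
                end = t.outcome_date or t.true_lmp + timedelta(
                    days=t.gestational_length_days
                )
                assert not (t.true_lmp <= ev.event_date <= end)

    def test_corruption_deterministic(self, registry, clean_sim):
        cfg, result = clean_sim
        noisy_cfg = SimConfig(
            random_seed=9, n_persons=cfg.n_persons, p_missing_gw=0.3, p_outlier_gw=0.3
        )
        c1 = corrupt_events(result.events, noisy_cfg, registry)
        c2 = corrupt_events(result.events, noisy_cfg, registry)
        assert c1 == c2
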