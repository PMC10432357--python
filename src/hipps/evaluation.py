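"""Ground-truth recovery metrics for simulated cohorts (testing plumbing)."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .episode_merge import HippsEpisode
from .synth_cohort import GroundTruthPregnancy

__all__ = ["RecoveryReport", "evaluate_recovery", "pair_truth_to_episodes"]


@dataclass
class RecoveryReport:
    n_truth: int
    n_episodes: int
    n_matched: int
    n_outcome_correct: int
    n_exact_start: int  # inferred start equals true LMP exactly
    n_start_evaluable: int  # matched episodes with a point start estimate

    @property
    def episode_recall(self) -> float:
        return self.n_matched / self.n_truth if self.n_truth else float("nan")

    @property
    def outcome_accuracy(self) -> float:
        return (
            self.n_outcome_correct / self.n_matched if self.n_matched else float("nan")
        )


def pair_truth_to_episodes(
    truths: Sequence[GroundTruthPregnancy], episodes: Sequence[HippsEpisode]
) -> list[tuple[GroundTruthPregnancy, Optional[HippsEpisode]]]:
    """Greedy in-order pairing: each truth takes the first unconsumed episode
    whose interval intersects [true_lmp, true_lmp + length]."""
    pairs: list[tuple[GroundTruthPregnancy, Optional[HippsEpisode]]] = []
    remaining = sorted(episodes, key=lambda e: (e.start_date, e.end_date))
    for t in sorted(truths, key=lambda t: t.true_lmp):
        t_end = t.outcome_date or t.true_lmp
        match = None
        for ep in remaining:
            if ep.start_date <= t_end and t.true_lmp <= ep.end_date:
                match = ep
                break
        if match is not None:
            remaining.remove(match)
        pairs.append((t, match))
    return pairs


def evaluate_recovery(
    truth: Sequence[GroundTruthPregnancy], episodes: Sequence[HippsEpisode]
) -> RecoveryReport:
    truths_by_person: dict[str, list[GroundTruthPregnancy]] = {}
    for t in truth:
        truths_by_person.setdefault(t.person_id, []).append(t)
    eps_by_person: dict[str, list[HippsEpisode]] = {}
    for e in episodes:
        eps_by_person.setdefault(e.person_id, []).append(e)

    n_matched = n_outcome = n_exact = n_evaluable = 0
    for person_id, truths in truths_by_person.items():
        pairs = pair_truth_to_episodes(truths, eps_by_person.get(person_id, []))
        for t, ep in pairs:
            if ep is None:
                continue
            n_matched += 1
            if ep.outcome_category is t.outcome_category:
                n_outcome += 1
            if ep.inferred_start_date is not None:
                n_evaluable += 1
                if ep.inferred_start_date == t.true_lmp:
                    n_exact += 1
    return RecoveryReport(
        n_truth=len(truth),
        n_episodes=len(episodes),
        n_matched=n_matched,
        n_outcome_correct=n_outcome,
        n_exact_start=n_exact,
        n_start_evaluable=n_evaluable,
    )
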