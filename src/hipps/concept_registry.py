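"""Typed registry of concept classifications and gestational-timing metadata.

The registry is the single source of truth for how a raw ``concept_id`` is
interpreted downstream: as a pregnancy outcome, a week-resolution gestational
age record ("Gestation period, X weeks"), a ranged timing concept used for
episode progression or start-date inference, or a COVID-19 test/diagnosis
code.  It also carries every tunable rule constant (``HierarchyConfig``).

Real OMOP concept sets can be dropped in via the JSON format documented in
:func:`load_registry`; :func:`default_registry` ships a fully valid fixture
used by the simulator and the test suite.  Timing windows other than the
estriol window (months 3.75-5.5) are plausible stand-ins, not vetted values.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Mapping, Optional, Sequence

__all__ = [
    "OutcomeCategory",
    "TimingUsage",
    "GestationWeekConcept",
    "TimingConcept",
    "CovidConcepts",
    "HierarchyConfig",
    "ConceptRegistry",
    "RegistryError",
    "parse_gestation_week",
    "load_registry",
    "save_registry",
    "default_registry",
]

REGISTRY_SCHEMA_VERSION = 1

#: Hard cap on parseable gestation weeks; chosen above the 43-week live-birth
#: maximum so legitimate post-term records survive while recording noise
#: (e.g. week 52) is rejected.
MAX_GESTATION_WEEK = 44

DAYS_PER_WEEK = 7


class RegistryError(ValueError):
    """A registry file or in-memory registry violates a structural invariant."""


class OutcomeCategory(Enum):
    """Pregnancy outcome categories, ordered by assessment priority."""

    LIVE_BIRTH = "LIVE_BIRTH"
    STILLBIRTH = "STILLBIRTH"
    ECTOPIC = "ECTOPIC"
    SPONTANEOUS_ABORTION = "SPONTANEOUS_ABORTION"
    INDUCED_ABORTION = "INDUCED_ABORTION"
    DELIVERY_ONLY = "DELIVERY_ONLY"

    @property
    def priority(self) -> int:
        """Rank in the assessment hierarchy; lower value = higher priority."""
        return _PRIORITY[self]


_PRIORITY = {c: i for i, c in enumerate(OutcomeCategory)}

#: Categories whose outcome implies a delivery-length pregnancy.
DELIVERY_CATEGORIES = frozenset(
    {
        OutcomeCategory.LIVE_BIRTH,
        OutcomeCategory.STILLBIRTH,
        OutcomeCategory.DELIVERY_ONLY,
    }
)


class TimingUsage(Enum):
    """How a ranged timing concept participates in inference."""

    GR3M = "GR3m"  # start-date range evidence (span >1 week, <3 months)
    PROGRESSION = "PROGRESSION"  # progression-scan episode building
    HELD_OUT = "HELD_OUT"  # external validation only (span 4-10 months)


_GW_PATTERN = re.compile(r"\AGestation period, (\d+) week(s)?\Z")


def parse_gestation_week(concept_name: str) -> Optional[int]:
    """Extract X from a concept named ``"Gestation period, X weeks"``.

    Returns ``None`` when the name does not match (the caller excludes the
    concept from the gestation-week set).  The singular form ``"1 week"`` is
    accepted; a plural marker on week 1 or missing plural elsewhere is not.
    """
    m = _GW_PATTERN.match(concept_name)
    if not m:
        return None
    week = int(m.group(1))
    plural = m.group(2) is not None
    if plural != (week != 1):
        return None
    return week


@dataclass(frozen=True)
class GestationWeekConcept:
    """A week-resolution gestational-age concept ("Gestation period, X weeks")."""

    concept_id: int
    week: int

    def __post_init__(self) -> None:
        if not 1 <= self.week <= MAX_GESTATION_WEEK:
            raise RegistryError(
                f"concept {self.concept_id}: gestation week {self.week} "
                f"outside [1, {MAX_GESTATION_WEEK}]"
            )


@dataclass(frozen=True)
class TimingConcept:
    """A concept expected to occur in a known gestational-month window.

    ``min_month``/``max_month`` are real months from the pregnancy start
    (LMP).  Usage determines the admissible window span: progression and
    GR3m concepts must span more than one week and at most three months;
    held-out validation concepts span four to ten months.
    """

    concept_id: int
    min_month: float
    max_month: float
    usage: TimingUsage
    concept_name: str = ""

    def __post_init__(self) -> None:
        cid = self.concept_id
        if not (0 < self.min_month <= self.max_month <= 10):
            raise RegistryError(
                f"concept {cid}: window [{self.min_month}, {self.max_month}] "
                "must satisfy 0 < min <= max <= 10 months"
            )
        span = self.max_month - self.min_month
        if self.usage in (TimingUsage.GR3M, TimingUsage.PROGRESSION):
            if span > 3:
                raise RegistryError(
                    f"concept {cid}: {self.usage.value} span {span:.2f} months "
                    "exceeds 3 months"
                )
            if span * 30.44 <= DAYS_PER_WEEK:
                raise RegistryError(
                    f"concept {cid}: {self.usage.value} span {span:.2f} months "
                    "must exceed 1 week"
                )
        else:  # HELD_OUT
            if not 4 <= span <= 10:
                raise RegistryError(
                    f"concept {cid}: HELD_OUT span {span:.2f} months "
                    "outside [4, 10]"
                )

    @property
    def span_months(self) -> float:
        return self.max_month - self.min_month


@dataclass(frozen=True)
class CovidConcepts:
    """COVID-19 laboratory-test and diagnosis concept sets."""

    pcr_ag_test: frozenset[int] = frozenset()
    covid_diagnosis: frozenset[int] = frozenset()


def _default_separation_matrix() -> dict[tuple[OutcomeCategory, OutcomeCategory], int]:
    """Minimum days between retained outcome pairs, keyed (earlier, later).

    Live-birth and stillbirth pairs use the published constants (182 / 168
    days; a stillbirth must follow a live birth by >=168 days or precede it
    by >=182 days).  All other pairs default to 56 days and are configurable.
    """
    lb = OutcomeCategory.LIVE_BIRTH
    sb = OutcomeCategory.STILLBIRTH
    matrix: dict[tuple[OutcomeCategory, OutcomeCategory], int] = {}
    for earlier in OutcomeCategory:
        for later in OutcomeCategory:
            matrix[(earlier, later)] = 56
    matrix[(lb, lb)] = 182
    matrix[(sb, sb)] = 168
    matrix[(lb, sb)] = 168  # stillbirth following a live birth
    matrix[(sb, lb)] = 182  # live birth following a stillbirth
    return matrix


def _default_term_windows() -> dict[OutcomeCategory, tuple[int, int]]:
    # Only the live-birth maximum (301 days / 43 weeks) is externally
    # anchored; the remaining bounds are configurable defaults.
    return {
        OutcomeCategory.LIVE_BIRTH: (140, 301),
        OutcomeCategory.STILLBIRTH: (140, 301),
        OutcomeCategory.ECTOPIC: (14, 84),
        OutcomeCategory.SPONTANEOUS_ABORTION: (14, 168),
        OutcomeCategory.INDUCED_ABORTION: (14, 168),
        OutcomeCategory.DELIVERY_ONLY: (140, 301),
    }


@dataclass(frozen=True)
class HierarchyConfig:
    """Every rule constant used by episode construction and scoring.

    ``days_per_month`` makes month arithmetic explicit (365.25/12 ~ 30.44);
    the source rules mix "2 months" and "60 days", so the conversion must be
    a single configurable number.
    """

    priority: tuple[OutcomeCategory, ...] = tuple(OutcomeCategory)
    pairwise_min_separation_days: Mapping[
        tuple[OutcomeCategory, OutcomeCategory], int
    ] = field(default_factory=_default_separation_matrix)
    term_duration_days: Mapping[OutcomeCategory, tuple[int, int]] = field(
        default_factory=_default_term_windows
    )
    retry_days: int = 60
    max_episode_months: int = 12
    max_episodes_per_year: int = 5
    days_per_month: float = 30.44
    outcome_match_window_days: int = 14
    esd_disjunctive_outlier_removal: bool = False

    def __post_init__(self) -> None:
        if self.retry_days <= 0 or self.max_episode_months <= 0:
            raise RegistryError("retry_days and max_episode_months must be positive")
        if self.days_per_month <= 0:
            raise RegistryError("days_per_month must be positive")
        for pair, days in self.pairwise_min_separation_days.items():
            if days <= 0:
                raise RegistryError(f"separation for {pair} must be positive")
        for cat, (lo, hi) in self.term_duration_days.items():
            if not 0 < lo < hi:
                raise RegistryError(f"term window for {cat} must satisfy 0 < min < max")

    def min_separation(
        self, earlier: OutcomeCategory, later: OutcomeCategory
    ) -> int:
        return self.pairwise_min_separation_days[(earlier, later)]

    def term_window(self, category: OutcomeCategory) -> tuple[int, int]:
        return self.term_duration_days[category]

    @property
    def min_delivery_days(self) -> int:
        """Earliest plausible gestational length of a delivery outcome."""
        return min(
            self.term_duration_days[c][0] for c in DELIVERY_CATEGORIES
        )


@dataclass(frozen=True)
class ConceptRegistry:
    """Concept classifications plus the rule configuration.

    Invariant: a concept_id belongs to at most one of the outcome,
    gestation-week, and timing maps, and held-out timing concepts never
    share an id with progression/GR3m concepts (enforced at construction).
    """

    outcomes: Mapping[int, OutcomeCategory]
    gestation_weeks: Mapping[int, GestationWeekConcept]
    timing: Mapping[int, TimingConcept]
    covid: CovidConcepts = field(default_factory=CovidConcepts)
    hierarchy: HierarchyConfig = field(default_factory=HierarchyConfig)

    def __post_init__(self) -> None:
        maps = {
            "outcomes": set(self.outcomes),
            "gestation_weeks": set(self.gestation_weeks),
            "timing": set(self.timing),
        }
        names = list(maps)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                dupes = maps[a] & maps[b]
                if dupes:
                    raise RegistryError(
                        f"concept_id {sorted(dupes)[0]} registered in both "
                        f"{a} and {b}"
                    )
        for cid, tc in self.timing.items():
            if tc.concept_id != cid:
                raise RegistryError(f"timing map key {cid} != concept_id {tc.concept_id}")
        for cid, gw in self.gestation_weeks.items():
            if gw.concept_id != cid:
                raise RegistryError(f"GW map key {cid} != concept_id {gw.concept_id}")

    def timing_by_usage(self, usage: TimingUsage) -> list[TimingConcept]:
        return sorted(
            (t for t in self.timing.values() if t.usage is usage),
            key=lambda t: (t.min_month, t.max_month, t.concept_id),
        )

    @property
    def progression_concepts(self) -> list[TimingConcept]:
        return self.timing_by_usage(TimingUsage.PROGRESSION)

    @property
    def gr3m_concepts(self) -> list[TimingConcept]:
        return self.timing_by_usage(TimingUsage.GR3M)

    @property
    def held_out_concepts(self) -> list[TimingConcept]:
        return self.timing_by_usage(TimingUsage.HELD_OUT)

    def week_for(self, concept_id: int) -> Optional[int]:
        gw = self.gestation_weeks.get(concept_id)
        return gw.week if gw else None

    def with_hierarchy(self, hierarchy: HierarchyConfig) -> "ConceptRegistry":
        return replace(self, hierarchy=hierarchy)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def _hierarchy_to_json(h: HierarchyConfig) -> dict:
    return {
        "priority": [c.value for c in h.priority],
        "pairwise_min_separation_days": {
            f"{a.value}|{b.value}": d
            for (a, b), d in sorted(
                h.pairwise_min_separation_days.items(),
                key=lambda kv: (kv[0][0].value, kv[0][1].value),
            )
        },
        "term_duration_days": {
            c.value: list(w) for c, w in sorted(
                h.term_duration_days.items(), key=lambda kv: kv[0].value
            )
        },
        "retry_days": h.retry_days,
        "max_episode_months": h.max_episode_months,
        "max_episodes_per_year": h.max_episodes_per_year,
        "days_per_month": h.days_per_month,
        "outcome_match_window_days": h.outcome_match_window_days,
        "esd_disjunctive_outlier_removal": h.esd_disjunctive_outlier_removal,
    }


def _hierarchy_from_json(obj: dict) -> HierarchyConfig:
    kwargs: dict = {}
    if "priority" in obj:
        kwargs["priority"] = tuple(OutcomeCategory(v) for v in obj["priority"])
    if "pairwise_min_separation_days" in obj:
        matrix = dict(_default_separation_matrix())
        for key, days in obj["pairwise_min_separation_days"].items():
            a, b = key.split("|")
            matrix[(OutcomeCategory(a), OutcomeCategory(b))] = int(days)
        kwargs["pairwise_min_separation_days"] = matrix
    if "term_duration_days" in obj:
        windows = dict(_default_term_windows())
        for key, (lo, hi) in obj["term_duration_days"].items():
            windows[OutcomeCategory(key)] = (int(lo), int(hi))
        kwargs["term_duration_days"] = windows
    for name in (
        "retry_days",
        "max_episode_months",
        "max_episodes_per_year",
        "days_per_month",
        "outcome_match_window_days",
        "esd_disjunctive_outlier_removal",
    ):
        if name in obj:
            kwargs[name] = obj[name]
    return HierarchyConfig(**kwargs)


def registry_to_json(registry: ConceptRegistry) -> dict:
    return {
        "schema_version": REGISTRY_SCHEMA_VERSION,
        "outcomes": {
            str(cid): cat.value for cid, cat in sorted(registry.outcomes.items())
        },
        "gestation_weeks": {
            str(cid): gw.week for cid, gw in sorted(registry.gestation_weeks.items())
        },
        "timing": {
            str(cid): {
                "min_month": tc.min_month,
                "max_month": tc.max_month,
                "usage": tc.usage.value,
                "concept_name": tc.concept_name,
            }
            for cid, tc in sorted(registry.timing.items())
        },
        "covid": {
            "pcr_ag_test": sorted(registry.covid.pcr_ag_test),
            "covid_diagnosis": sorted(registry.covid.covid_diagnosis),
        },
        "hierarchy": _hierarchy_to_json(registry.hierarchy),
    }


def registry_from_json(obj: dict) -> ConceptRegistry:
    try:
        outcomes = {
            int(cid): OutcomeCategory(cat)
            for cid, cat in obj.get("outcomes", {}).items()
        }
        gestation_weeks = {
            int(cid): GestationWeekConcept(int(cid), int(week))
            for cid, week in obj.get("gestation_weeks", {}).items()
        }
        timing = {
            int(cid): TimingConcept(
                concept_id=int(cid),
                min_month=float(spec["min_month"]),
                max_month=float(spec["max_month"]),
                usage=TimingUsage(spec["usage"]),
                concept_name=spec.get("concept_name", ""),
            )
            for cid, spec in obj.get("timing", {}).items()
        }
    except (KeyError, ValueError) as exc:
        if isinstance(exc, RegistryError):
            raise
        raise RegistryError(f"malformed registry entry: {exc}") from exc
    covid_obj = obj.get("covid", {})
    covid = CovidConcepts(
        pcr_ag_test=frozenset(int(c) for c in covid_obj.get("pcr_ag_test", [])),
        covid_diagnosis=frozenset(
            int(c) for c in covid_obj.get("covid_diagnosis", [])
        ),
    )
    hierarchy = _hierarchy_from_json(obj.get("hierarchy", {}))
    return ConceptRegistry(
        outcomes=outcomes,
        gestation_weeks=gestation_weeks,
        timing=timing,
        covid=covid,
        hierarchy=hierarchy,
    )


def load_registry(path: str | Path) -> ConceptRegistry:
    """Load and validate a registry from its JSON file.

    Top-level keys: ``outcomes`` (concept_id -> category), ``gestation_weeks``
    (concept_id -> week), ``timing`` (concept_id -> {min_month, max_month,
    usage}), ``covid`` ({pcr_ag_test, covid_diagnosis} id lists) and
    ``hierarchy`` (rule-constant overrides).  Any invariant violation raises
    :class:`RegistryError` naming the offending concept.
    """
    with open(path, "r", encoding="utf-8") as fh:
        obj = json.load(fh)
    version = obj.get("schema_version", REGISTRY_SCHEMA_VERSION)
    if version != REGISTRY_SCHEMA_VERSION:
        raise RegistryError(f"unsupported registry schema_version {version}")
    return registry_from_json(obj)


def save_registry(registry: ConceptRegistry, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(registry_to_json(registry), fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Bundled fixture registry
# ---------------------------------------------------------------------------

# Concept-id blocks for the fixture (synthetic ids, OMOP-sized).
GW_CONCEPT_BASE = 3048000  # GW concept for week w has id GW_CONCEPT_BASE + w
OUTCOME_CONCEPT_IDS: dict[OutcomeCategory, tuple[int, ...]] = {
    OutcomeCategory.LIVE_BIRTH: (4092289, 4093288),
    OutcomeCategory.STILLBIRTH: (4079844, 4079845),
    OutcomeCategory.ECTOPIC: (4128331, 4128332),
    OutcomeCategory.SPONTANEOUS_ABORTION: (4067106, 4067107),
    OutcomeCategory.INDUCED_ABORTION: (4081254, 4081255),
    OutcomeCategory.DELIVERY_ONLY: (4125611, 4125612),
}
COVID_TEST_CONCEPT_ID = 37310255
COVID_DIAGNOSIS_CONCEPT_ID = 37311061

_FIXTURE_TIMING: Sequence[tuple[int, str, float, float, TimingUsage]] = (
    # Progression concepts: tight windows marching through pregnancy.
    (4210001, "First trimester intake panel", 1.0, 2.0, TimingUsage.PROGRESSION),
    (4210002, "Nuchal translucency scan", 2.0, 3.0, TimingUsage.PROGRESSION),
    (4210003, "Second trimester anatomy survey", 3.5, 4.5, TimingUsage.PROGRESSION),
    (4210004, "Maternal serum screen, mid-gestation", 5.0, 6.0, TimingUsage.PROGRESSION),
    (4210005, "Glucose tolerance test, 3 specimens", 6.0, 7.0, TimingUsage.PROGRESSION),
    (4210006, "Group B streptococcus culture", 8.0, 9.0, TimingUsage.PROGRESSION),
    # Ranged (GR3m) start-date evidence; the estriol window is the one
    # externally anchored value (months 3.75-5.5).
    (4220001, "Estriol measurement", 3.75, 5.5, TimingUsage.GR3M),
    (4220002, "Cell-free fetal DNA screen", 1.5, 2.5, TimingUsage.GR3M),
    (4220003, "Fetal growth ultrasound, third trimester", 6.5, 8.0, TimingUsage.GR3M),
    # Held-out validation concepts (wide windows, inference-excluded).
    (4230001, "Polyhydramnios", 6.0, 10.0, TimingUsage.HELD_OUT),
    (4230002, "Pregnancy-related pelvic girdle pain", 4.0, 9.0, TimingUsage.HELD_OUT),
    (4230003, "Routine antenatal supervision", 0.5, 10.0, TimingUsage.HELD_OUT),
)


def default_registry(hierarchy: HierarchyConfig | None = None) -> ConceptRegistry:
    """Bundled fixture registry with every concept role populated.

    Gestation-week concepts cover weeks 1-44; outcome categories each have
    two concept ids; timing concepts cover progression, GR3m, and held-out
    roles.  Timing windows other than estriol's are documented stand-ins.
    """
    outcomes = {
        cid: cat for cat, cids in OUTCOME_CONCEPT_IDS.items() for cid in cids
    }
    gestation_weeks = {
        GW_CONCEPT_BASE + w: GestationWeekConcept(GW_CONCEPT_BASE + w, w)
        for w in range(1, MAX_GESTATION_WEEK + 1)
    }
    timing = {
        cid: TimingConcept(cid, lo, hi, usage, concept_name=name)
        for cid, name, lo, hi, usage in _FIXTURE_TIMING
    }
    covid = CovidConcepts(
        pcr_ag_test=frozenset({COVID_TEST_CONCEPT_ID}),
        covid_diagnosis=frozenset({COVID_DIAGNOSIS_CONCEPT_ID}),
    )
    return ConceptRegistry(
        outcomes=outcomes,
        gestation_weeks=gestation_weeks,
        timing=timing,
        covid=covid,
        hierarchy=hierarchy or HierarchyConfig(),
    )


def gw_concept_name(week: int) -> str:
    unit = "week" if week == 1 else "weeks"
    return f"Gestation period, {week} {unit}"
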