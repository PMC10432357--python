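"""Data model and I/O for OMOP-lite event tables; candidate-person filtering.

Five clinical domains are modeled (condition, procedure, observation,
measurement, drug).  Each domain's CSV uses its OMOP 5.3.1 column names
(``condition_concept_id``, ``condition_start_date``, ...); a generic
``concept_id``/``event_date`` header is accepted as a fallback.  Dates are
handled at day resolution throughout.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import pandas as pd

__all__ = [
    "PersonRecord",
    "ClinicalEvent",
    "EventTable",
    "LoadReport",
    "FormatError",
    "read_events",
    "read_persons",
    "filter_candidates",
    "write_episode_table",
    "read_episode_table",
    "EPISODE_COLUMNS",
]

DOMAINS = ("condition", "procedure", "observation", "measurement", "drug")


class FormatError(ValueError):
    """An input file does not match the expected tabular format."""


@dataclass(frozen=True)
class PersonRecord:
    person_id: str
    birth_date: Optional[date]
    sex: str = "unknown"  # {"female", "male", "other", "unknown"}
    race: str = "unknown"
    ethnicity: str = "unknown"


@dataclass(frozen=True, order=True)
class ClinicalEvent:
    """One dated, person-linked occurrence of a vocabulary concept."""

    person_id: str
    event_date: date
    concept_id: int
    domain: str
    concept_name: str = ""
    value: str = ""


@dataclass(frozen=True)
class LoadReport:
    path: str
    table_kind: str
    n_rows: int
    n_loaded: int
    n_dropped_bad_date: int

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"{self.path} [{self.table_kind}]: {self.n_loaded}/{self.n_rows} rows "
            f"loaded, {self.n_dropped_bad_date} row(s) dropped (unparseable date)"
        )


class EventTable:
    """Ordered collection of :class:`ClinicalEvent` with per-person access.

    Events are kept stably sorted by (person_id, event_date, concept_id,
    domain, value); downstream algorithms rely on this deterministic order.
    """

    def __init__(self, events: Iterable[ClinicalEvent] = ()) -> None:
        self._events: tuple[ClinicalEvent, ...] = tuple(
            sorted(
                events,
                key=lambda e: (
                    e.person_id,
                    e.event_date,
                    e.concept_id,
                    e.domain,
                    e.value,
                    e.concept_name,
                ),
            )
        )

    def __len__(self) -> int:
        return len(self._events)

    def __iter__(self) -> Iterator[ClinicalEvent]:
        return iter(self._events)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, EventTable) and self._events == other._events

    @property
    def events(self) -> tuple[ClinicalEvent, ...]:
        return self._events

    def person_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self._events:
            seen.setdefault(e.person_id, None)
        return list(seen)

    def for_person(self, person_id: str) -> list[ClinicalEvent]:
        return [e for e in self._events if e.person_id == person_id]

    def by_person(self) -> dict[str, list[ClinicalEvent]]:
        grouped: dict[str, list[ClinicalEvent]] = {}
        for e in self._events:
            grouped.setdefault(e.person_id, []).append(e)
        return grouped

    def concat(self, other: "EventTable") -> "EventTable":
        return EventTable(self._events + other._events)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "person_id": [e.person_id for e in self._events],
                "event_date": [e.event_date.isoformat() for e in self._events],
                "concept_id": [e.concept_id for e in self._events],
                "domain": [e.domain for e in self._events],
                "concept_name": [e.concept_name for e in self._events],
                "value": [e.value for e in self._events],
            }
        )


# OMOP 5.3.1 column names per table kind, with generic fallbacks.
_TABLE_COLUMNS: dict[str, dict[str, Sequence[str]]] = {
    "condition": {
        "concept_id": ("condition_concept_id", "concept_id"),
        "event_date": ("condition_start_date", "event_date"),
        "concept_name": ("condition_concept_name", "concept_name"),
        "value": ("value",),
    },
    "procedure": {
        "concept_id": ("procedure_concept_id", "concept_id"),
        "event_date": ("procedure_date", "event_date"),
        "concept_name": ("procedure_concept_name", "concept_name"),
        "value": ("value",),
    },
    "observation": {
        "concept_id": ("observation_concept_id", "concept_id"),
        "event_date": ("observation_date", "event_date"),
        "concept_name": ("observation_concept_name", "concept_name"),
        "value": ("value_as_string", "value"),
    },
    "measurement": {
        "concept_id": ("measurement_concept_id", "concept_id"),
        "event_date": ("measurement_date", "event_date"),
        "concept_name": ("measurement_concept_name", "concept_name"),
        "value": ("value_source_value", "value_as_string", "value"),
    },
    "drug": {
        "concept_id": ("drug_concept_id", "concept_id"),
        "event_date": ("drug_exposure_start_date", "event_date"),
        "concept_name": ("drug_concept_name", "concept_name"),
        "value": ("value",),
    },
}

#: Canonical OMOP-like file name per table kind (used by the simulator/CLI).
TABLE_FILENAMES = {
    "condition": "condition_occurrence.csv",
    "procedure": "procedure_occurrence.csv",
    "observation": "observation.csv",
    "measurement": "measurement.csv",
    "drug": "drug_exposure.csv",
}


def _pick_column(columns: Sequence[str], candidates: Sequence[str]) -> Optional[str]:
    for c in candidates:
        if c in columns:
            return c
    return None


def read_events(path: str | Path, table_kind: str) -> tuple[EventTable, LoadReport]:
    """Read one OMOP-lite table into an :class:`EventTable`.

    Rows with unparseable dates are dropped and counted in the
    :class:`LoadReport`.  A missing required column raises
    :class:`FormatError` naming the column; an empty file yields an empty
    table.
    """
    if table_kind not in _TABLE_COLUMNS:
        raise ValueError(f"unknown table_kind {table_kind!r}; expected one of {DOMAINS}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return EventTable(), LoadReport(str(path), table_kind, 0, 0, 0)

    spec = _TABLE_COLUMNS[table_kind]
    if "person_id" not in frame.columns:
        raise FormatError(f"{path}: missing required column: person_id")
    concept_col = _pick_column(frame.columns, spec["concept_id"])
    if concept_col is None:
        raise FormatError(
            f"{path}: missing required column: {spec['concept_id'][0]}"
        )
    date_col = _pick_column(frame.columns, spec["event_date"])
    if date_col is None:
        raise FormatError(
            f"{path}: missing required column: {spec['event_date'][0]}"
        )
    name_col = _pick_column(frame.columns, spec["concept_name"])
    value_col = _pick_column(frame.columns, spec["value"])

    n_rows = len(frame)
    parsed = pd.to_datetime(frame[date_col], errors="coerce", format="mixed")
    keep = parsed.notna()
    n_dropped = int((~keep).sum())
    sub = frame.loc[keep]
    dates = parsed.loc[keep]
    events = [
        ClinicalEvent(
            person_id=str(pid),
            event_date=d.date(),
            concept_id=int(float(cid)),
            domain=table_kind,
            concept_name=str(name) if name_col else "",
            value=str(val) if value_col else "",
        )
        for pid, d, cid, name, val in zip(
            sub["person_id"],
            dates,
            sub[concept_col],
            sub[name_col] if name_col else [""] * len(sub),
            sub[value_col] if value_col else [""] * len(sub),
        )
    ]
    table = EventTable(events)
    report = LoadReport(str(path), table_kind, n_rows, len(table), n_dropped)
    return table, report


def read_events_dir(input_dir: str | Path) -> tuple[EventTable, list[LoadReport]]:
    """Read every present OMOP-lite event table under ``input_dir``."""
    input_dir = Path(input_dir)
    table = EventTable()
    reports: list[LoadReport] = []
    for kind in DOMAINS:
        path = input_dir / TABLE_FILENAMES[kind]
        if path.exists():
            t, report = read_events(path, kind)
            table = table.concat(t)
            reports.append(report)
    return table, reports


def read_persons(path: str | Path) -> list[PersonRecord]:
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return []
    if "person_id" not in frame.columns:
        raise FormatError(f"{path}: missing required column: person_id")
    persons = []
    for _, row in frame.iterrows():
        raw_birth = row.get("birth_date", "") or row.get("birth_datetime", "")
        birth: Optional[date]
        try:
            birth = datetime.strptime(str(raw_birth)[:10], "%Y-%m-%d").date()
        except ValueError:
            birth = None
        persons.append(
            PersonRecord(
                person_id=str(row["person_id"]),
                birth_date=birth,
                sex=str(row.get("sex", "") or "unknown").lower(),
                race=str(row.get("race", "") or "unknown"),
                ethnicity=str(row.get("ethnicity", "") or "unknown"),
            )
        )
    return persons


def write_persons(persons: Sequence[PersonRecord], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["person_id", "birth_date", "sex", "race", "ethnicity"])
        for p in persons:
            writer.writerow(
                [
                    p.person_id,
                    p.birth_date.isoformat() if p.birth_date else "",
                    p.sex,
                    p.race,
                    p.ethnicity,
                ]
            )


def completed_years(birth_date: date, at: date) -> int:
    """Age in completed years at ``at`` (floor)."""
    years = at.year - birth_date.year
    if (at.month, at.day) < (birth_date.month, birth_date.day):
        years -= 1
    return years


@dataclass
class CandidateFilterReport:
    n_persons: int = 0
    n_included: int = 0
    n_missing_sex: int = 0
    n_missing_birth_date: int = 0
    n_excluded_sex: int = 0
    n_excluded_age: int = 0


def filter_candidates(
    persons: Iterable[PersonRecord],
    reference_date: date,
    min_age: int = 15,
    max_age: int = 55,
) -> tuple[set[str], CandidateFilterReport]:
    """Ids of persons recorded female and aged [min_age, max_age] inclusive.

    Persons with missing sex or birth date are excluded and counted in the
    report rather than raising.
    """
    report = CandidateFilterReport()
    included: set[str] = set()
    for p in persons:
        report.n_persons += 1
        if p.sex in ("", "unknown", "other"):
            report.n_missing_sex += 1
            continue
        if p.birth_date is None:
            report.n_missing_birth_date += 1
            continue
        if p.sex != "female":
            report.n_excluded_sex += 1
            continue
        age = completed_years(p.birth_date, reference_date)
        if not min_age <= age <= max_age:
            report.n_excluded_age += 1
            continue
        included.add(p.person_id)
        report.n_included += 1
    return included, report


# ---------------------------------------------------------------------------
# Final episode table I/O
# ---------------------------------------------------------------------------

EPISODE_COLUMNS = (
    "person_id",
    "episode_id",
    "inferred_start_date",
    "recorded_start_date",
    "end_date",
    "outcome_category",
    "hip_flag",
    "pps_flag",
    "concordance_score",
    "precision_category",
    "precision_days",
)


def _fmt_date(d: Optional[date]) -> str:
    return d.isoformat() if d is not None else ""


def write_episode_table(episodes: Sequence, path: str | Path) -> None:
    """Write final episodes as CSV with the documented column order.

    Accepts any objects exposing the :data:`EPISODE_COLUMNS` attributes
    (in practice :class:`hipps.episode_merge.HippsEpisode`); round-trips
    losslessly through :func:`read_episode_table`.
    """
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(EPISODE_COLUMNS)
        for ep in episodes:
            outcome = ep.outcome_category
            writer.writerow(
                [
                    ep.person_id,
                    ep.episode_id,
                    _fmt_date(ep.inferred_start_date),
                    _fmt_date(ep.recorded_start_date),
                    _fmt_date(ep.end_date),
                    outcome.value if outcome is not None else "",
                    int(bool(ep.hip_flag)),
                    int(bool(ep.pps_flag)),
                    "" if ep.concordance_score is None else int(ep.concordance_score),
                    ep.precision_category or "",
                    "" if ep.precision_days is None else int(ep.precision_days),
                ]
            )


def read_episode_table(path: str | Path) -> list:
    """Read a final episode CSV back into :class:`HippsEpisode` rows."""
    from .concept_registry import OutcomeCategory
    from .episode_merge import HippsEpisode

    def _parse_date(s: str) -> Optional[date]:
        return date.fromisoformat(s) if s else None

    episodes = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(EPISODE_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise FormatError(f"{path}: missing required column: {sorted(missing)[0]}")
        for row in reader:
            episodes.append(
                HippsEpisode(
                    person_id=row["person_id"],
                    episode_id=row["episode_id"],
                    start_date=_parse_date(row["recorded_start_date"]),
                    end_date=_parse_date(row["end_date"]),
                    inferred_start_date=_parse_date(row["inferred_start_date"]),
                    recorded_start_date=_parse_date(row["recorded_start_date"]),
                    outcome_category=(
                        OutcomeCategory(row["outcome_category"])
                        if row["outcome_category"]
                        else None
                    ),
                    hip_flag=bool(int(row["hip_flag"])),
                    pps_flag=bool(int(row["pps_flag"])),
                    concordance_score=(
                        int(row["concordance_score"])
                        if row["concordance_score"] != ""
                        else None
                    ),
                    precision_category=row["precision_category"] or None,
                    precision_days=(
                        int(row["precision_days"])
                        if row["precision_days"] != ""
                        else None
                    ),
                )
            )
    return episodes
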