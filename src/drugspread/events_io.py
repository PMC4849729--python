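"""Event tables for drug studies and drug adoptions by diseases.

The raw material of every analysis stage is a set of timestamped triplets:
a *study* record pairs a drug with a study and a date (plus the diseases
annotated on that study), and an *adoption* record marks the first time a
disease is paired with a drug.  Times are stored as fractional calendar
years so that publication dates and trial start dates share one axis.
"""

from __future__ import annotations

import datetime as _dt
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "StudyRecord",
    "AdoptionRecord",
    "ObservationWindow",
    "EventTable",
    "parse_time",
    "read_study_table",
    "write_study_table",
    "read_adoption_table",
    "write_adoption_table",
    "derive_adoptions",
    "birth_times",
    "DEFAULT_WINDOW",
]

_BARE_YEAR = re.compile(r"^\d{4}$")
_FRACTIONAL_YEAR = re.compile(r"^\d{4}\.\d+$")


class FormatError(ValueError):
    """Raised when an input table violates the expected layout."""


@dataclass(frozen=True, order=True)
class StudyRecord:
    """One (drug, study) event at a fractional-year timestamp.

    ``diseases`` holds the disease tokens annotated on the study; it may be
    empty, in which case the study still counts toward study-accumulation
    curves but contributes no adoption.
    """

    time: float
    drug_id: str
    study_id: str
    diseases: frozenset = field(default_factory=frozenset, compare=False)

    def __post_init__(self):
        if not self.drug_id or not self.study_id:
            raise ValueError("drug_id and study_id must be non-empty")


@dataclass(frozen=True, order=True)
class AdoptionRecord:
    """First pairing of a drug with a disease, at a fractional-year time."""

    time: float
    drug_id: str
    disease_id: str


@dataclass(frozen=True)
class ObservationWindow:
    """Half-open observation span; ``t_max`` is the right-censoring time."""

    t_start: float
    t_max: float

    def __post_init__(self):
        if not self.t_start < self.t_max:
            raise ValueError(f"t_start ({self.t_start}) must be < t_max ({self.t_max})")

    def contains(self, t: float) -> bool:
        return self.t_start <= t <= self.t_max


#: End of year 2010, the default last-observation time.
DEFAULT_WINDOW = ObservationWindow(t_start=1900.0, t_max=2010.999)


def parse_time(text: str) -> float:
    """Parse a date string into a fractional year.

    Accepted forms: a bare year (``1998`` -> 1998.0), an already fractional
    year (``1998.25``), or an ISO-8601 date (``1998-07-01`` -> year +
    (day_of_year - 1)/365.25).
    """
    text = text.strip()
    if _BARE_YEAR.match(text):
        return float(text)
    if _FRACTIONAL_YEAR.match(text):
        return float(text)
    try:
        d = _dt.date.fromisoformat(text)
    except ValueError as exc:
        raise ValueError(f"unparseable date: {text!r}") from exc
    day_of_year = (d - _dt.date(d.year, 1, 1)).days
    return d.year + day_of_year / 365.25


class EventTable:
    """Immutable, canonically ordered collection of study records.

    Iteration order is (time, drug_id, study_id) so that every downstream
    artifact is bit-reproducible.
    """

    def __init__(self, records: Iterable[StudyRecord]):
        self._records = tuple(sorted(records, key=lambda r: (r.time, r.drug_id, r.study_id)))
        seen = set()
        for r in self._records:
            key = (r.drug_id, r.study_id)
            if key in seen:
                raise ValueError(f"duplicate (drug, study) pair: {key}")
            seen.add(key)
        self._by_drug: dict[str, list[StudyRecord]] = {}
        for r in self._records:
            self._by_drug.setdefault(r.drug_id, []).append(r)

    @property
    def records(self) -> tuple[StudyRecord, ...]:
        return self._records

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self):
        return iter(self._records)

    def __eq__(self, other) -> bool:
        if not isinstance(other, EventTable):
            return NotImplemented
        return self._records == other._records

    @property
    def drugs(self) -> tuple[str, ...]:
        return tuple(sorted(self._by_drug))

    def for_drug(self, drug_id: str) -> tuple[StudyRecord, ...]:
        if drug_id not in self._by_drug:
            raise KeyError(f"unknown drug: {drug_id!r}")
        return tuple(self._by_drug[drug_id])


def read_study_table(path: str | Path, window: ObservationWindow = DEFAULT_WINDOW) -> EventTable:
    """Read a TSV study table into an :class:`EventTable`.

    Expected columns: ``drug_id``, ``study_id``, ``date`` (ISO-8601, bare
    year, or fractional year) and ``diseases`` (semicolon-separated, may be
    empty).  Rows outside ``window`` are dropped (count logged); duplicate
    (drug, study) rows collapse to the earliest date.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"drug_id", "study_id", "date", "diseases"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required column(s): {sorted(missing)}")

    records: dict[tuple[str, str], StudyRecord] = {}
    n_dropped = 0
    for idx, row in enumerate(df.itertuples(index=False)):
        try:
            t = parse_time(row.date)
        except ValueError as exc:
            # +2: one for the header line, one for 1-based numbering
            raise FormatError(f"{path}: line {idx + 2}: {exc}") from exc
        diseases = frozenset(tok for tok in row.diseases.split(";") if tok)
        rec = StudyRecord(time=t, drug_id=row.drug_id, study_id=row.study_id, diseases=diseases)
        if not window.contains(t):
            n_dropped += 1
            continue
        key = (rec.drug_id, rec.study_id)
        if key in records and records[key].time <= rec.time:
            continue
        records[key] = rec
    if n_dropped:
        logger.info("read_study_table: dropped %d row(s) outside window", n_dropped)
    return EventTable(records.values())


def write_study_table(events: EventTable, path: str | Path) -> None:
    """Write an event table as TSV; dates stored as fractional years."""
    rows = [
        {
            "drug_id": r.drug_id,
            "study_id": r.study_id,
            "date": repr(float(r.time)),
            "diseases": ";".join(sorted(r.diseases)),
        }
        for r in events
    ]
    pd.DataFrame(rows, columns=["drug_id", "study_id", "date", "diseases"]).to_csv(
        path, sep="\t", index=False
    )


def derive_adoptions(events: EventTable) -> tuple[AdoptionRecord, ...]:
    """First (drug, disease) pairings: the minimum study time over all
    studies mentioning both, in canonical (time, drug, disease) order."""
    first: dict[tuple[str, str], float] = {}
    for r in events:
        for disease in r.diseases:
            key = (r.drug_id, disease)
            if key not in first or r.time < first[key]:
                first[key] = r.time
    recs = [AdoptionRecord(time=t, drug_id=d, disease_id=dis) for (d, dis), t in first.items()]
    return tuple(sorted(recs, key=lambda a: (a.time, a.drug_id, a.disease_id)))


def birth_times(events: EventTable) -> dict[str, float]:
    """Per drug, the minimum study time (the drug's *birth*)."""
    births: dict[str, float] = {}
    for r in events:
        if r.drug_id not in births or r.time < births[r.drug_id]:
            births[r.drug_id] = r.time
    return births


def write_adoption_table(adoptions: Iterable[AdoptionRecord], path: str | Path) -> None:
    rows = [
        {"drug_id": a.drug_id, "disease_id": a.disease_id, "year": repr(float(a.time))}
        for a in sorted(adoptions, key=lambda a: (a.time, a.drug_id, a.disease_id))
    ]
    pd.DataFrame(rows, columns=["drug_id", "disease_id", "year"]).to_csv(path, sep="\t", index=False)


def read_adoption_table(path: str | Path) -> tuple[AdoptionRecord, ...]:
    df = pd.read_csv(path, sep="\t", dtype={"drug_id": str, "disease_id": str, "year": float})
    required = {"drug_id", "disease_id", "year"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required column(s): {sorted(missing)}")
    recs = [
        AdoptionRecord(time=row.year, drug_id=row.drug_id, disease_id=row.disease_id)
        for row in df.itertuples(index=False)
    ]
    return tuple(sorted(recs, key=lambda a: (a.time, a.drug_id, a.disease_id)))


def adoption_times_by_drug(
    adoptions: Iterable[AdoptionRecord],
) -> dict[str, dict[str, float]]:
    """Index adoptions as drug -> {disease -> adoption time}."""
    out: dict[str, dict[str, float]] = {}
    for a in adoptions:
        out.setdefault(a.drug_id, {})[a.disease_id] = a.time
    return out
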