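"""Domain record types and file I/O.

Raw field observations are tabular: social-interaction events (initiator,
recipient, date, location, behaviour class), co-location sampling records,
per-individual-year metadata, fitness outcomes, and predator-sighting effort.
Records are read from headed CSV files into lightweight dataclasses; dates are
ISO-8601 in files and proleptic-Gregorian ordinal days in memory so season
windows can be tested without timezone or format ambiguity.

Interaction participants that could not be identified in the field are kept as
the reserved id token :data:`UNKNOWN` — they are excluded later, by the
filtering stage, so that exclusion counts are reportable.
"""

from __future__ import annotations

import csv
import datetime as _dt
from dataclasses import dataclass, fields as _dc_fields
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

#: Reserved id token for an unidentified interaction participant.
UNKNOWN = "UNKNOWN"

BEHAVIOURS = ("affiliative", "agonistic", "other")
SEXES = ("F", "M")
AGE_CLASSES = ("adult", "yearling")
ELEVATIONS = ("higher", "lower")

#: Sentinel for a missing value in CSV files.
NA_TOKEN = "NA"


class RecordError(ValueError):
    """Raised for a malformed or invariant-violating row; carries line number."""


def _parse_date(text: str, line: int) -> int:
    try:
        return _dt.date.fromisoformat(text).toordinal()
    except ValueError as exc:
        raise RecordError(f"line {line}: invalid date {text!r}") from exc


def date_to_iso(ordinal: int) -> str:
    return _dt.date.fromordinal(ordinal).isoformat()


def month_of(ordinal: int) -> int:
    """Calendar month (1-12) of an ordinal day."""
    return _dt.date.fromordinal(ordinal).month


@dataclass(frozen=True)
class InteractionRecord:
    initiator: str
    recipient: str
    date: int  # ordinal day
    location: str
    behaviour: str

    def validate(self, line: int = -1) -> None:
        if self.behaviour not in BEHAVIOURS:
            raise RecordError(f"line {line}: unknown behaviour {self.behaviour!r}")
        if (
            self.initiator == self.recipient
            and self.initiator != UNKNOWN
        ):
            raise RecordError(
                f"line {line}: initiator equals recipient ({self.initiator!r})"
            )

    @property
    def any_unknown(self) -> bool:
        return self.initiator == UNKNOWN or self.recipient == UNKNOWN


@dataclass(frozen=True)
class ColocationRecord:
    individual: str
    date: int
    location: str

    def validate(self, line: int = -1) -> None:
        if not self.individual:
            raise RecordError(f"line {line}: empty individual id")


@dataclass(frozen=True)
class IndividualYear:
    id: str
    year: int
    sex: str
    age_class: str
    colony: str
    elevation: str
    june_mass: float | None
    august_mass: float | None
    n_observations: int

    def validate(self, line: int = -1) -> None:
        if self.sex not in SEXES:
            raise RecordError(f"line {line}: sex must be one of {SEXES}")
        if self.age_class not in AGE_CLASSES:
            raise RecordError(f"line {line}: age_class must be one of {AGE_CLASSES}")
        if self.elevation not in ELEVATIONS:
            raise RecordError(f"line {line}: elevation must be one of {ELEVATIONS}")
        if self.n_observations < 0:
            raise RecordError(f"line {line}: n_observations < 0")


@dataclass(frozen=True)
class FitnessRecord:
    id: str
    year: int
    summer_survival: int | None
    hibernation_survival: int | None
    weaned: int | None
    n_weaned: int | None

    def validate(self, line: int = -1) -> None:
        for name in ("summer_survival", "hibernation_survival", "weaned"):
            v = getattr(self, name)
            if v is not None and v not in (0, 1):
                raise RecordError(f"line {line}: {name} must be 0/1/NA")
        # the litter-size channel conditions on a weaned litter
        if self.n_weaned is not None and self.n_weaned < 1:
            raise RecordError(f"line {line}: n_weaned must be >= 1 when present")


@dataclass(frozen=True)
class PredationRecord:
    colony: str
    year: int
    predators_seen: int
    observation_time: float  # hours

    def validate(self, line: int = -1) -> None:
        if self.predators_seen < 0:
            raise RecordError(f"line {line}: predators_seen < 0")
        if not self.observation_time > 0:
            raise RecordError(f"line {line}: observation_time must be > 0")


RECORD_TYPES = {
    "interaction": InteractionRecord,
    "colocation": ColocationRecord,
    "individual_year": IndividualYear,
    "fitness": FitnessRecord,
    "predation": PredationRecord,
}

_HEADERS = {
    "interaction": ["initiator", "recipient", "date", "location", "behaviour"],
    "colocation": ["individual", "date", "location"],
    "individual_year": [
        "id", "year", "sex", "age_class", "colony", "elevation",
        "june_mass", "august_mass", "n_observations",
    ],
    "fitness": [
        "id", "year", "summer_survival", "hibernation_survival",
        "weaned", "n_weaned",
    ],
    "predation": ["colony", "year", "predators_seen", "observation_time"],
}

_DATE_FIELDS = {"date"}
_INT_FIELDS = {
    "year", "n_observations", "predators_seen", "n_weaned",
    "summer_survival", "hibernation_survival", "weaned",
}
_FLOAT_FIELDS = {"june_mass", "august_mass", "observation_time"}
_OPTIONAL_FIELDS = {
    "june_mass", "august_mass", "summer_survival", "hibernation_survival",
    "weaned", "n_weaned",
}


def _convert(name: str, text: str, line: int):
    text = text.strip()
    if name in _OPTIONAL_FIELDS and (text == NA_TOKEN or text == ""):
        return None
    try:
        if name in _DATE_FIELDS:
            return _parse_date(text, line)
        if name in _INT_FIELDS:
            return int(text)
        if name in _FLOAT_FIELDS:
            return float(text)
    except RecordError:
        raise
    except ValueError as exc:
        raise RecordError(f"line {line}: bad value {text!r} for {name}") from exc
    return text


def read_records(path: str | Path, schema: str) -> list:
    """Read a headed CSV of one record kind into validated dataclasses.

    Malformed rows raise :class:`RecordError` naming the 1-based file line;
    no row is ever silently dropped. UNKNOWN participant ids are preserved.
    """
    cls = RECORD_TYPES.get(schema)
    if cls is None:
        raise ValueError(f"unknown schema {schema!r}; expected {sorted(RECORD_TYPES)}")
    expected = _HEADERS[schema]
    out = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise RecordError(f"{path}: empty file") from None
        if [h.strip() for h in header] != expected:
            raise RecordError(
                f"{path}: header {header!r} does not match schema "
                f"{schema!r} ({expected!r})"
            )
        for line_no, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != len(expected):
                raise RecordError(
                    f"line {line_no}: expected {len(expected)} fields, got {len(row)}"
                )
            values = {
                name: _convert(name, cell, line_no)
                for name, cell in zip(expected, row)
            }
            rec = cls(**values)
            rec.validate(line_no)
            out.append(rec)
    return out


def _cell(value) -> str:
    if value is None:
        return NA_TOKEN
    return str(value)


def write_records(records: Sequence, path: str | Path, schema: str) -> None:
    """Write records of one kind to CSV (inverse of :func:`read_records`)."""
    expected = _HEADERS[schema]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(expected)
        for rec in records:
            row = []
            for name in expected:
                value = getattr(rec, name)
                if name in _DATE_FIELDS:
                    value = date_to_iso(value)
                row.append(_cell(value))
            writer.writerow(row)


def write_graphml(network: nx.DiGraph, path: str | Path) -> None:
    """Write a directed weighted interaction network to GraphML.

    Edge attribute ``weight`` carries the integer interaction count;
    re-reading with :func:`read_graphml` reproduces the adjacency exactly.
    """
    if network.number_of_nodes() < 1:
        raise ValueError("refusing to write an empty network")
    nx.write_graphml(network, str(path))


def read_graphml(path: str | Path) -> nx.DiGraph:
    g = nx.read_graphml(str(path))
    out = nx.DiGraph()
    out.add_nodes_from(g.nodes())
    for u, v, data in g.edges(data=True):
        out.add_edge(u, v, weight=int(data.get("weight", 1)))
    return out


def records_to_frame(records: Iterable) -> "pandas.DataFrame":  # noqa: F821
    """Convenience: a DataFrame view of a homogeneous record list."""
    import pandas as pd

    records = list(records)
    if not records:
        return pd.DataFrame()
    cols = [f.name for f in _dc_fields(records[0])]
    return pd.DataFrame([[getattr(r, c) for c in cols] for r in records], columns=cols)
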