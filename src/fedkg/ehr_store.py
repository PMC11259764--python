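"""Per-hospital EHR tables and their patient-visit-treatment triple projection.

Holds a trimmed OMOP-style relational layout (person, visit_occurrence, and
the four event tables) and projects it into an RDF graph with a three-level
patient → visit → event structure, each event linked to its vocabulary
concept.  Dates are day-granular ISO-8601; intervals elsewhere in the package
are closed on both ends.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from rdflib import Graph, Literal, Namespace, RDF, URIRef
from rdflib.namespace import XSD

from ._util import parse_date

SEXES = frozenset({"female", "male"})
EVENT_KINDS = frozenset({"diagnosis", "measurement", "drug", "procedure"})

# event table file name -> event kind
EVENT_TABLES = {
    "condition_occurrence.csv": "diagnosis",
    "measurement.csv": "measurement",
    "drug_exposure.csv": "drug",
    "procedure_occurrence.csv": "procedure",
}

FEDKG = Namespace("urn:fedkg:vocab#")


class StoreError(ValueError):
    """Referential or field-level violation in an EHR store."""


def resource_uri(hospital_id: str, kind: str, local_id: str) -> str:
    """URI-like resource identifier ``<hospital>/<entity-kind>/<local-id>``."""
    return f"{hospital_id}/{kind}/{local_id}"


@dataclass(frozen=True)
class PersonRecord:
    person_id: str
    identity: str  # raw citizen-identity string; never leaves the hospital
    birth_year: int
    sex: str

    def __post_init__(self):
        if not self.identity:
            raise StoreError(f"person {self.person_id!r}: empty identity")
        if not 1900 <= self.birth_year <= dt.date.today().year:
            raise StoreError(
                f"person {self.person_id!r}: implausible birth_year {self.birth_year}"
            )
        if self.sex not in SEXES:
            raise StoreError(f"person {self.person_id!r}: unknown sex {self.sex!r}")


@dataclass(frozen=True)
class VisitRecord:
    visit_id: str
    person_id: str
    hospital_id: str
    visit_date: dt.date
    department: str


@dataclass(frozen=True)
class EventRecord:
    event_id: str
    visit_id: str
    kind: str
    concept_id: str
    value: Optional[float]
    unit: Optional[str]
    event_date: dt.date

    def __post_init__(self):
        if self.kind not in EVENT_KINDS:
            raise StoreError(f"event {self.event_id!r}: unknown kind {self.kind!r}")
        if self.kind == "measurement":
            if self.value is None or not self.unit:
                raise StoreError(
                    f"measurement {self.event_id!r} must carry value and unit"
                )
        elif self.value is not None or self.unit:
            raise StoreError(
                f"{self.kind} event {self.event_id!r} must not carry value/unit"
            )


@dataclass
class EHRStore:
    """One hospital's validated record collections."""

    hospital_id: str
    persons: dict[str, PersonRecord] = field(default_factory=dict)
    visits: dict[str, VisitRecord] = field(default_factory=dict)
    events: dict[str, EventRecord] = field(default_factory=dict)

    def validate(self, concepts=None) -> "EHRStore":
        for v in self.visits.values():
            if v.person_id not in self.persons:
                raise StoreError(
                    f"visit {v.visit_id!r} references missing person {v.person_id!r}"
                )
            if v.hospital_id != self.hospital_id:
                raise StoreError(
                    f"visit {v.visit_id!r} belongs to hospital {v.hospital_id!r}, "
                    f"store is {self.hospital_id!r}"
                )
        for e in self.events.values():
            if e.visit_id not in self.visits:
                raise StoreError(
                    f"event {e.event_id!r} references missing visit {e.visit_id!r}"
                )
            if concepts is not None and e.concept_id not in concepts:
                raise StoreError(
                    f"event {e.event_id!r}: concept {e.concept_id!r} not in vocabulary"
                )
        return self

    # -- convenience views ---------------------------------------------
    def visits_of(self, person_id: str) -> list[VisitRecord]:
        if person_id not in self.persons:
            raise StoreError(f"unknown person {person_id!r}")
        return sorted(
            (v for v in self.visits.values() if v.person_id == person_id),
            key=lambda v: (v.visit_date, v.visit_id),
        )

    def events_of_visit(self, visit_id: str) -> list[EventRecord]:
        return sorted(
            (e for e in self.events.values() if e.visit_id == visit_id),
            key=lambda e: (e.event_date, e.event_id),
        )


def patient_timeline(
    store: EHRStore, person_id: str
) -> list[tuple[VisitRecord, list[EventRecord]]]:
    """Chronological visit sequence with attached events.

    Visits sort by date then visit_id; each visit's events sort by event
    date then event_id.  Invariant under input row permutation.
    """
    return [(v, store.events_of_visit(v.visit_id)) for v in store.visits_of(person_id)]


# -- table IO ----------------------------------------------------------


def load_store(directory, hospital_id: Optional[str] = None, concepts=None) -> EHRStore:
    """Load one hospital's CSV tables into a validated store.

    Requires ``person.csv`` and ``visit_occurrence.csv``; event tables are
    optional (an absent table contributes zero events).
    """
    directory = Path(directory)
    person_path = directory / "person.csv"
    visit_path = directory / "visit_occurrence.csv"
    if not person_path.exists() or not visit_path.exists():
        raise StoreError(f"{directory}: person.csv and visit_occurrence.csv required")

    persons: dict[str, PersonRecord] = {}
    for row in pd.read_csv(person_path, dtype=str, keep_default_na=False).itertuples(
        index=False
    ):
        if row.person_id in persons:
            raise StoreError(f"duplicate person_id {row.person_id!r}")
        persons[row.person_id] = PersonRecord(
            person_id=row.person_id,
            identity=row.identity,
            birth_year=int(row.birth_year),
            sex=row.sex,
        )

    visits: dict[str, VisitRecord] = {}
    for row in pd.read_csv(visit_path, dtype=str, keep_default_na=False).itertuples(
        index=False
    ):
        if row.visit_id in visits:
            raise StoreError(f"duplicate visit_id {row.visit_id!r}")
        visits[row.visit_id] = VisitRecord(
            visit_id=row.visit_id,
            person_id=row.person_id,
            hospital_id=row.hospital_id,
            visit_date=parse_date(row.visit_date),
            department=row.department,
        )
    if hospital_id is None:
        hospitals = {v.hospital_id for v in visits.values()}
        if len(hospitals) > 1:
            raise StoreError(f"mixed hospital_ids in visit table: {sorted(hospitals)}")
        hospital_id = hospitals.pop() if hospitals else directory.name

    events: dict[str, EventRecord] = {}
    for fname, kind in EVENT_TABLES.items():
        path = directory / fname
        if not path.exists():
            continue
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        for row in df.itertuples(index=False):
            if row.event_id in events:
                raise StoreError(f"duplicate event_id {row.event_id!r}")
            value = unit = None
            if kind == "measurement":
                value = float(row.value)
                unit = row.unit
            events[row.event_id] = EventRecord(
                event_id=row.event_id,
                visit_id=row.visit_id,
                kind=kind,
                concept_id=row.concept_id,
                value=value,
                unit=unit,
                event_date=parse_date(row.event_date),
            )

    return EHRStore(
        hospital_id=hospital_id, persons=persons, visits=visits, events=events
    ).validate(concepts=concepts)


def write_store(store: EHRStore, directory) -> None:
    """Write the store back to its CSV layout (UTF-8, RFC-4180)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "person_id": p.person_id,
                "identity": p.identity,
                "birth_year": p.birth_year,
                "sex": p.sex,
            }
            for p in sorted(store.persons.values(), key=lambda p: p.person_id)
        ],
        columns=["person_id", "identity", "birth_year", "sex"],
    ).to_csv(directory / "person.csv", index=False)
    pd.DataFrame(
        [
            {
                "visit_id": v.visit_id,
                "person_id": v.person_id,
                "hospital_id": v.hospital_id,
                "visit_date": v.visit_date.isoformat(),
                "department": v.department,
            }
            for v in sorted(store.visits.values(), key=lambda v: v.visit_id)
        ],
        columns=["visit_id", "person_id", "hospital_id", "visit_date", "department"],
    ).to_csv(directory / "visit_occurrence.csv", index=False)
    for fname, kind in EVENT_TABLES.items():
        rows = []
        for e in sorted(store.events.values(), key=lambda e: e.event_id):
            if e.kind != kind:
                continue
            row = {
                "event_id": e.event_id,
                "visit_id": e.visit_id,
                "concept_id": e.concept_id,
                "event_date": e.event_date.isoformat(),
            }
            if kind == "measurement":
                row["value"] = f"{e.value:.1f}"
                row["unit"] = e.unit
            rows.append(row)
        columns = ["event_id", "visit_id", "concept_id", "event_date"]
        if kind == "measurement":
            columns = ["event_id", "visit_id", "concept_id", "value", "unit", "event_date"]
        pd.DataFrame(rows, columns=columns).to_csv(directory / fname, index=False)


# -- triple projection -------------------------------------------------

_KIND_CLASS = {
    "diagnosis": FEDKG.DiagnosisEvent,
    "measurement": FEDKG.MeasurementEvent,
    "drug": FEDKG.DrugEvent,
    "procedure": FEDKG.ProcedureEvent,
}


def _uri(hospital_id: str, kind: str, local_id: str) -> URIRef:
    return URIRef("urn:fedkg:" + resource_uri(hospital_id, kind, local_id))


def to_triples(store: EHRStore) -> Graph:
    """Project the store into its patient-visit-treatment RDF graph.

    Triple budget per entity: 1 per person (type), 3 per visit (type,
    hasVisit, visitDate), 4 per non-measurement event (type, hasEvent,
    hasConcept, eventDate) and 6 per measurement event (adds hasValue,
    hasUnit).
    """
    g = Graph()
    g.bind("fedkg", FEDKG)
    h = store.hospital_id
    for p in store.persons.values():
        g.add((_uri(h, "person", p.person_id), RDF.type, FEDKG.Patient))
    for v in store.visits.values():
        vu = _uri(h, "visit", v.visit_id)
        g.add((vu, RDF.type, FEDKG.Visit))
        g.add((_uri(h, "person", v.person_id), FEDKG.hasVisit, vu))
        g.add((vu, FEDKG.visitDate, Literal(v.visit_date, datatype=XSD.date)))
    for e in store.events.values():
        eu = _uri(h, "event", e.event_id)
        g.add((eu, RDF.type, _KIND_CLASS[e.kind]))
        g.add((_uri(h, "visit", e.visit_id), FEDKG.hasEvent, eu))
        g.add((eu, FEDKG.hasConcept, URIRef(f"urn:fedkg:concept/{e.concept_id}")))
        g.add((eu, FEDKG.eventDate, Literal(e.event_date, datatype=XSD.date)))
        if e.kind == "measurement":
            g.add((eu, FEDKG.hasValue, Literal(e.value, datatype=XSD.double)))
            g.add((eu, FEDKG.hasUnit, Literal(e.unit)))
    return g


def expected_triple_count(store: EHRStore) -> int:
    n = len(store.persons) + 3 * len(store.visits)
    for e in store.events.values():
        n += 6 if e.kind == "measurement" else 4
    return n


def canonical_triples(store: EHRStore) -> str:
    """Deterministic N-Triples serialization: one line per triple, sorted."""
    g = to_triples(store)
    lines = sorted(
        f"{s.n3()} {p.n3()} {o.n3()} ." for s, p, o in g
    )
    return "\n".join(lines) + ("\n" if lines else "")
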