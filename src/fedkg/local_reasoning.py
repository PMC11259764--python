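"""Rule-based reasoning over one hospital's store.

Four concerns live here: the cohort-entry screen (who may join a
collaborative process), per-visit atomic finding derivation from diagnoses,
measurements, drugs and procedures, abstraction of those findings into
value-free hypernym-level intermediate findings, and the chronicity rule
that operationalizes sustained kidney dysfunction: two abnormal kidney
findings at least ``window_days`` (default 90, i.e. three months) apart with
no normal kidney-function observation strictly between them.  A normal
observation between two abnormal ones resets the chain, guarding against
transient dysfunction such as post-surgical recovery.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import yaml

from .alignment import HashedIdentity
from .ehr_store import EHRStore, EventRecord, VisitRecord, patient_timeline
from .vocabulary import HypernymMap

# reason codes for the eligibility screen
NO_KIDNEY_TEST = "NO_KIDNEY_TEST"
NEPHROLOGY_VISIT = "NEPHROLOGY_VISIT"
KIDNEY_DIAGNOSIS = "KIDNEY_DIAGNOSIS"


class RuleError(ValueError):
    """Malformed rule set."""


# unit conversions understood by measurement rules: (from, to) -> factor.
# 1 mg/mmol of urine albumin-to-creatinine ratio equals 8.84 mg/g.
_UNIT_FACTORS = {
    ("mg/mmol", "mg/g"): 8.84,
    ("mg/g", "mg/mmol"): 1.0 / 8.84,
}


def convert_value(value: float, from_unit: str, to_unit: str) -> float:
    if from_unit == to_unit:
        return value
    try:
        return value * _UNIT_FACTORS[(from_unit, to_unit)]
    except KeyError:
        raise RuleError(f"no conversion from {from_unit!r} to {to_unit!r}") from None


@dataclass(frozen=True)
class Finding:
    """A raw, provenance-bearing per-visit conclusion (never exported)."""

    person_id: str
    visit_id: str
    date: dt.date
    concept_id: str
    positive: bool
    provenance: str  # diagnosis | measurement | drug | procedure
    source_event_id: str
    rule_id: Optional[str] = None


@dataclass(frozen=True)
class IntermediateFinding:
    """The privacy-isolated twin of a finding: hypernym + date + label only.

    Carries no value, no unit, no provenance, no raw identity and no leaf
    concept — this is the privacy contract for everything that crosses a
    hospital boundary.
    """

    hashed_identity: str
    date: dt.date
    hypernym_concept_id: str
    positive: bool


@dataclass(frozen=True)
class MeasurementRule:
    rule_id: str
    concept_id: str  # measurement concept the rule listens to
    comparator: str  # '<' or '>'
    threshold: float
    unit: str
    finding_concept_id: str
    emit_negative: bool = False  # emit a positive=False observation when not triggered

    def __post_init__(self):
        if self.comparator not in {"<", ">"}:
            raise RuleError(f"rule {self.rule_id!r}: comparator must be < or >")

    def evaluate(self, event: EventRecord) -> Optional[bool]:
        """True → abnormal finding, False → normal observation, None → silent."""
        value = convert_value(event.value, event.unit, self.unit)
        triggered = value < self.threshold if self.comparator == "<" else value > self.threshold
        if triggered:
            return True
        return False if self.emit_negative else None


@dataclass(frozen=True)
class MappingRule:
    """Diagnosis/drug/procedure concept → finding concept."""

    rule_id: str
    event_kind: str
    concept_id: str
    finding_concept_id: str


@dataclass(frozen=True)
class RuleSet:
    measurement_rules: tuple[MeasurementRule, ...] = ()
    mapping_rules: tuple[MappingRule, ...] = ()
    window_days: int = 90
    kidney_hypernym: str = "abnormal_kidney_function"
    abnormal_kidney_findings: frozenset[str] = frozenset()
    kidney_measurements: frozenset[str] = frozenset()
    kidney_diagnoses: frozenset[str] = frozenset()
    nephrology_departments: frozenset[str] = frozenset({"nephrology"})
    risk_hypernyms: frozenset[str] = frozenset()

    def measurement_rules_for(self, concept_id: str) -> tuple[MeasurementRule, ...]:
        return tuple(r for r in self.measurement_rules if r.concept_id == concept_id)

    def mapping_rules_for(self, kind: str, concept_id: str) -> tuple[MappingRule, ...]:
        return tuple(
            r
            for r in self.mapping_rules
            if r.event_kind == kind and r.concept_id == concept_id
        )


def load_rules(path) -> RuleSet:
    """Load a YAML rule file into a :class:`RuleSet`."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    mrules = tuple(
        MeasurementRule(
            rule_id=r["rule_id"],
            concept_id=r["concept_id"],
            comparator=r["comparator"],
            threshold=float(r["threshold"]),
            unit=r["unit"],
            finding_concept_id=r["finding_concept_id"],
            emit_negative=bool(r.get("emit_negative", False)),
        )
        for r in doc.get("measurement_rules", [])
    )
    prules = tuple(
        MappingRule(
            rule_id=r["rule_id"],
            event_kind=r["event_kind"],
            concept_id=r["concept_id"],
            finding_concept_id=r["finding_concept_id"],
        )
        for r in doc.get("mapping_rules", [])
    )
    return RuleSet(
        measurement_rules=mrules,
        mapping_rules=prules,
        window_days=int(doc.get("window_days", 90)),
        kidney_hypernym=doc.get("kidney_hypernym", "abnormal_kidney_function"),
        abnormal_kidney_findings=frozenset(doc.get("abnormal_kidney_findings", [])),
        kidney_measurements=frozenset(doc.get("kidney_measurements", [])),
        kidney_diagnoses=frozenset(doc.get("kidney_diagnoses", [])),
        nephrology_departments=frozenset(
            doc.get("nephrology_departments", ["nephrology"])
        ),
        risk_hypernyms=frozenset(doc.get("risk_hypernyms", [])),
    )


def save_rules(rules: RuleSet, path) -> None:
    doc = {
        "measurement_rules": [
            {
                "rule_id": r.rule_id,
                "concept_id": r.concept_id,
                "comparator": r.comparator,
                "threshold": r.threshold,
                "unit": r.unit,
                "finding_concept_id": r.finding_concept_id,
                "emit_negative": r.emit_negative,
            }
            for r in rules.measurement_rules
        ],
        "mapping_rules": [
            {
                "rule_id": r.rule_id,
                "event_kind": r.event_kind,
                "concept_id": r.concept_id,
                "finding_concept_id": r.finding_concept_id,
            }
            for r in rules.mapping_rules
        ],
        "window_days": rules.window_days,
        "kidney_hypernym": rules.kidney_hypernym,
        "abnormal_kidney_findings": sorted(rules.abnormal_kidney_findings),
        "kidney_measurements": sorted(rules.kidney_measurements),
        "kidney_diagnoses": sorted(rules.kidney_diagnoses),
        "nephrology_departments": sorted(rules.nephrology_departments),
        "risk_hypernyms": sorted(rules.risk_hypernyms),
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


# -- eligibility screen ------------------------------------------------


@dataclass(frozen=True)
class EligibilityDecision:
    person_id: str
    eligible: bool
    reasons: tuple[str, ...] = ()


def initiation_protocol(
    store: EHRStore, person_id: str, rules: RuleSet
) -> EligibilityDecision:
    """Cohort-entry screen for the overlooked-kidney-disease application.

    Eligible iff the patient has at least one kidney-function measurement,
    no visit to a nephrology department, and no kidney-disease diagnosis on
    record.  Reason codes enumerate every failed clause.
    """
    reasons: list[str] = []
    has_kidney_test = False
    nephrology = False
    kidney_dx = False
    for visit, events in patient_timeline(store, person_id):
        if visit.department in rules.nephrology_departments:
            nephrology = True
        for e in events:
            if e.kind == "measurement" and e.concept_id in rules.kidney_measurements:
                has_kidney_test = True
            if e.kind == "diagnosis" and e.concept_id in rules.kidney_diagnoses:
                kidney_dx = True
    if not has_kidney_test:
        reasons.append(NO_KIDNEY_TEST)
    if nephrology:
        reasons.append(NEPHROLOGY_VISIT)
    if kidney_dx:
        reasons.append(KIDNEY_DIAGNOSIS)
    return EligibilityDecision(
        person_id=person_id, eligible=not reasons, reasons=tuple(reasons)
    )


# -- finding derivation ------------------------------------------------


def derive_visit_findings(
    visit: VisitRecord, events: Sequence[EventRecord], rules: RuleSet
) -> tuple[Finding, ...]:
    """Atomic, independent findings for one visit (no cross-visit state)."""
    findings: list[Finding] = []
    for e in sorted(events, key=lambda e: (e.event_date, e.event_id)):
        if e.kind == "measurement":
            for rule in rules.measurement_rules_for(e.concept_id):
                verdict = rule.evaluate(e)
                if verdict is None:
                    continue
                findings.append(
                    Finding(
                        person_id=visit.person_id,
                        visit_id=visit.visit_id,
                        date=e.event_date,
                        concept_id=rule.finding_concept_id,
                        positive=verdict,
                        provenance="measurement",
                        source_event_id=e.event_id,
                        rule_id=rule.rule_id,
                    )
                )
        else:
            for rule in rules.mapping_rules_for(e.kind, e.concept_id):
                findings.append(
                    Finding(
                        person_id=visit.person_id,
                        visit_id=visit.visit_id,
                        date=e.event_date,
                        concept_id=rule.finding_concept_id,
                        positive=True,
                        provenance=e.kind,
                        source_event_id=e.event_id,
                        rule_id=rule.rule_id,
                    )
                )
    return tuple(findings)


def derive_person_findings(
    store: EHRStore,
    person_id: str,
    rules: RuleSet,
    start: Optional[dt.date] = None,
    end: Optional[dt.date] = None,
) -> tuple[Finding, ...]:
    """All findings for one patient, optionally restricted to [start, end]."""
    out: list[Finding] = []
    for visit, events in patient_timeline(store, person_id):
        kept = [
            e
            for e in events
            if (start is None or e.event_date >= start)
            and (end is None or e.event_date <= end)
        ]
        out.extend(derive_visit_findings(visit, kept, rules))
    return tuple(out)


def abstract_findings(
    findings: Iterable[Finding],
    hypernym_map: HypernymMap,
    hashed_identity: HashedIdentity | str,
    on_unmapped: str = "drop",
) -> tuple[IntermediateFinding, ...]:
    """Hypernymize findings and deduplicate per (date, hypernym, label).

    Unmapped leaf concepts are dropped by default (raw leaves must never be
    transmitted); ``on_unmapped='error'`` raises instead.  Output order is
    deterministic: by date, hypernym id, label.
    """
    digest = (
        hashed_identity.digest
        if isinstance(hashed_identity, HashedIdentity)
        else str(hashed_identity)
    )
    seen: set[tuple[dt.date, str, bool]] = set()
    out: list[IntermediateFinding] = []
    for f in findings:
        hyp = hypernym_map.hypernym_for(f.concept_id)
        if hyp is None:
            if on_unmapped == "error":
                raise RuleError(f"finding concept {f.concept_id!r} has no hypernym")
            continue
        key = (f.date, hyp, f.positive)
        if key in seen:
            continue
        seen.add(key)
        out.append(
            IntermediateFinding(
                hashed_identity=digest,
                date=f.date,
                hypernym_concept_id=hyp,
                positive=f.positive,
            )
        )
    out.sort(key=lambda i: (i.date, i.hypernym_concept_id, i.positive))
    return tuple(out)


# -- chronicity --------------------------------------------------------


@dataclass(frozen=True)
class ChronicityVerdict:
    met: bool
    first_met_date: Optional[dt.date] = None
    supporting_pair: Optional[tuple] = None  # (first abnormal, second abnormal)


def detect_ckd_criteria(
    findings: Sequence, window_days: int = 90
) -> ChronicityVerdict:
    """Chronicity rule over a kidney-finding timeline.

    ``findings`` are objects with a ``date`` and a boolean ``positive``
    (True = abnormal kidney finding, False = normal kidney-function
    observation).  Met iff two abnormal findings lie >= ``window_days``
    apart with no normal observation dated strictly between them; the
    comparison is inclusive at exactly ``window_days``.  Returns the
    earliest date at which the rule is first satisfied and one supporting
    pair for explanation.
    """
    by_date: dict[dt.date, dict[str, object]] = {}
    for f in findings:
        slot = by_date.setdefault(f.date, {"abnormal": None, "normal": False})
        if f.positive:
            if slot["abnormal"] is None:
                slot["abnormal"] = f
        else:
            slot["normal"] = True

    anchor = None  # earliest abnormal since the last reset
    for date in sorted(by_date):
        slot = by_date[date]
        abnormal = slot["abnormal"]
        if abnormal is not None:
            if anchor is not None and (date - anchor.date).days >= window_days:
                return ChronicityVerdict(
                    met=True, first_met_date=date, supporting_pair=(anchor, abnormal)
                )
            if anchor is None:
                anchor = abnormal
        if slot["normal"]:
            # a normal observation this day blocks any pair spanning it;
            # an abnormal on the same day may still anchor a later pair
            anchor = abnormal if abnormal is not None else None
    return ChronicityVerdict(met=False)
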