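"""The five-step collaborative reasoning process across simulated nodes.

1. Every node screens its patients with the cohort-entry protocol and
   broadcasts the eligible patients' initial kidney findings as online
   subgraphs (plus digest-only exclusion announcements).
2. The sponsoring node aligns patients by hashed identity.
3. The sponsor builds each patient's merged multicenter timeline and
   designates a region of interest (ROI) for every patient whose merged
   kidney findings satisfy the chronicity rule; ROIs are broadcast.
4. Every node re-derives findings restricted to the ROI, abstracts them to
   hypernyms, and broadcasts them as subgraphs (the visit-date pathway is
   included, findings outside the ROI are never exported).
5. The sponsor merges all rounds and performs summarization reasoning:
   chronicity verdict, group classification (multicenter-data vs
   transferred vs single-center), risk collection inside the ROI, and an
   evidence trail sufficient to re-derive the verdict.

Everything that crosses a node boundary goes through the hash-chained
ledger, so a single byte scan of the ledger covers the full exchange.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from ._util import canonical_json, parse_date
from .alignment import AlignmentTable, HashedIdentity, align_patients, hash_identity
from .collaboration import (
    Ledger,
    MergedPathway,
    OnlineSubgraph,
    Receipt,
    broadcast,
    build_online_subgraph,
    deserialize_subgraph,
    merge_remote,
    serialize_subgraph,
)
from .ehr_store import EHRStore, resource_uri
from .local_reasoning import (
    EligibilityDecision,
    Finding,
    RuleSet,
    abstract_findings,
    derive_person_findings,
    detect_ckd_criteria,
    initiation_protocol,
)
from .vocabulary import ConceptGraph, HypernymMap

GROUP_MULTICENTER = "multicenter_data"
GROUP_TRANSFERRED = "transferred"
GROUP_SINGLE_CENTER = "single_center"
GROUP_NONE = "none"

# reason codes that trigger consortium-wide exclusion
_GLOBAL_EXCLUSION_REASONS = {"NEPHROLOGY_VISIT", "KIDNEY_DIAGNOSIS"}


class ProtocolError(RuntimeError):
    pass


class SchemaError(ValueError):
    pass


@dataclass
class Node:
    """One hospital's deployment: store, vocabulary, abstraction map, rules."""

    hospital_id: str
    store: EHRStore
    graph: ConceptGraph
    hypernym_map: HypernymMap
    rules: RuleSet


@dataclass(frozen=True)
class ROI:
    """Disease-related observation window for one patient."""

    digest: str
    start: dt.date
    end: dt.date

    def __post_init__(self):
        if self.start > self.end:
            raise ProtocolError("ROI start after end")

    def contains(self, date: dt.date) -> bool:
        return self.start <= date <= self.end


@dataclass(frozen=True)
class RiskEvidence:
    concept_id: str
    date: dt.date
    origin: str


@dataclass(frozen=True)
class TrailEntry:
    date: dt.date
    concept_id: str
    positive: bool
    origin: str
    rule_id: Optional[str] = None
    role: str = "evidence"  # or "chronicity_pair"


@dataclass
class CDSResult:
    digest: str
    local_person_uri: Optional[str]
    ckd_met: bool
    first_met_date: Optional[dt.date]
    group: str
    roi: Optional[ROI]
    risks: tuple[RiskEvidence, ...] = ()
    evidence_trail: tuple[TrailEntry, ...] = ()
    visits: tuple[tuple[str, dt.date], ...] = ()  # (origin, date)
    transfer_date: Optional[dt.date] = None
    satisfying_hospital: Optional[str] = None


@dataclass
class RunResult:
    sponsor_id: str
    series_number: int
    results: dict  # digest -> CDSResult
    ledger: Ledger
    receipts: tuple[Receipt, ...]
    alignment: AlignmentTable
    eligibility: dict  # hospital_id -> tuple[EligibilityDecision, ...]
    rois: dict  # digest -> ROI
    excluded_digests: frozenset


class _PathObs:
    """Adapter exposing merged-pathway findings to the chronicity rule."""

    __slots__ = ("origin", "date", "concept_id", "positive")

    def __init__(self, origin, date, concept_id, positive):
        self.origin = origin
        self.date = date
        self.concept_id = concept_id
        self.positive = positive


class CollaborativeProcess:
    def __init__(
        self,
        nodes: Sequence[Node],
        sponsor_id: str,
        salt: str,
        salt_id: str = "consortium",
        series_number: int = 1,
    ):
        self.nodes = sorted(nodes, key=lambda n: n.hospital_id)
        ids = [n.hospital_id for n in self.nodes]
        if len(set(ids)) != len(ids):
            raise ProtocolError("duplicate hospital ids")
        if sponsor_id not in ids:
            raise ProtocolError(f"sponsor {sponsor_id!r} is not a registered node")
        self.sponsor_id = sponsor_id
        self.salt = salt
        self.salt_id = salt_id
        self.series_number = series_number
        self.ledger = Ledger()

    # -- helpers -------------------------------------------------------
    def _digests(self, node: Node) -> dict[str, HashedIdentity]:
        return {
            pid: hash_identity(node.store.persons[pid].identity, self.salt, self.salt_id)
            for pid in sorted(node.store.persons)
        }

    def _kidney_findings(self, node: Node, pid: str, start=None, end=None):
        findings = derive_person_findings(node.store, pid, node.rules, start, end)
        return tuple(
            f for f in findings if f.concept_id in node.rules.abnormal_kidney_findings
        )

    def _append(self, payload: dict) -> None:
        self.ledger.append(canonical_json(payload))

    # -- step 1: initiation round -------------------------------------
    def run_initiation_round(self):
        """Per-node eligibility screen plus initial kidney-finding subgraphs."""
        eligibility: dict[str, tuple[EligibilityDecision, ...]] = {}
        for node in self.nodes:
            if not node.rules.measurement_rules and not node.rules.mapping_rules:
                raise ProtocolError(
                    f"node {node.hospital_id!r} has no reasoning rules; aborting"
                )
            digests = self._digests(node)
            decisions = tuple(
                initiation_protocol(node.store, pid, node.rules)
                for pid in sorted(node.store.persons)
            )
            eligibility[node.hospital_id] = decisions
            excluded = sorted(
                {
                    digests[d.person_id].digest
                    for d in decisions
                    if set(d.reasons) & _GLOBAL_EXCLUSION_REASONS
                }
            )
            eligible = sorted(
                digests[d.person_id].digest for d in decisions if d.eligible
            )
            self._append(
                {
                    "type": "eligibility",
                    "origin": node.hospital_id,
                    "series": self.series_number,
                    "eligible": eligible,
                    "excluded": [
                        {
                            "digest": digests[d.person_id].digest,
                            "reasons": sorted(
                                set(d.reasons) & _GLOBAL_EXCLUSION_REASONS
                            ),
                        }
                        for d in sorted(
                            (d for d in decisions
                             if set(d.reasons) & _GLOBAL_EXCLUSION_REASONS),
                            key=lambda d: digests[d.person_id].digest,
                        )
                    ],
                }
            )
            for d in decisions:
                if not d.eligible:
                    continue  # ineligible patients never leave their node
                pid = d.person_id
                intermediate = abstract_findings(
                    self._kidney_findings(node, pid),
                    node.hypernym_map,
                    digests[pid],
                )
                subgraph = build_online_subgraph(
                    digest=digests[pid].digest,
                    salt_id=self.salt_id,
                    findings=intermediate,
                    visit_dates=[v.visit_date for v in node.store.visits_of(pid)],
                    series_number=self.series_number,
                    origin_hospital_id=node.hospital_id,
                    allowed_hypernyms=node.hypernym_map.allowed_hypernyms,
                    stage="initiation",
                )
                self.ledger.append(serialize_subgraph(subgraph).decode("utf-8"))
        return eligibility

    # -- ledger reads --------------------------------------------------
    def _collect(self):
        subgraphs: list[OnlineSubgraph] = []
        eligible: set[str] = set()
        excluded: set[str] = set()
        rois: dict[str, ROI] = {}
        import json as _json

        for payload in self.ledger.payloads():
            doc = _json.loads(payload)
            if doc.get("type") == "subgraph":
                subgraphs.append(deserialize_subgraph(payload))
            elif doc.get("type") == "eligibility":
                eligible.update(doc["eligible"])
                excluded.update(e["digest"] for e in doc["excluded"])
            elif doc.get("type") == "roi":
                for r in doc["rois"]:
                    rois[r["digest"]] = ROI(
                        digest=r["digest"],
                        start=parse_date(r["start"]),
                        end=parse_date(r["end"]),
                    )
        return subgraphs, eligible, excluded, rois

    # -- step 2+3: alignment and ROI designation -----------------------
    def designate_roi(self):
        subgraphs, eligible, excluded, _ = self._collect()
        process_digests = sorted(eligible - excluded)
        pathways: dict[str, MergedPathway] = {}
        for digest in process_digests:
            pathways[digest] = merge_remote(
                None,
                [s for s in subgraphs if s.digest == digest and s.stage == "initiation"],
                digest=digest,
            )
        sponsor = self._node(self.sponsor_id)
        kidney_hyp = sponsor.rules.kidney_hypernym
        rois: list[ROI] = []
        for digest in process_digests:
            obs = [
                _PathObs(o, d, c, p)
                for (o, d, c, p) in pathways[digest].findings
                if c == kidney_hyp
            ]
            verdict = detect_ckd_criteria(obs, sponsor.rules.window_days)
            if not verdict.met:
                continue
            abnormal_dates = [o.date for o in obs if o.positive]
            rois.append(
                ROI(digest=digest, start=min(abnormal_dates), end=max(abnormal_dates))
            )
        self._append(
            {
                "type": "roi",
                "origin": self.sponsor_id,
                "series": self.series_number,
                "rois": [
                    {"digest": r.digest, "start": r.start.isoformat(),
                     "end": r.end.isoformat()}
                    for r in rois
                ],
            }
        )
        return {r.digest: r for r in rois}

    # -- step 4: ROI-restricted local reasoning ------------------------
    def local_reasoning_round(self, rois: dict[str, "ROI"]):
        """Each node exports hypernym findings within the ROI.

        The node's visit-date pathway for the patient is included (dates
        only); events outside the ROI are never processed for export.
        """
        for node in self.nodes:
            digests = self._digests(node)
            by_digest = {digests[pid].digest: pid for pid in sorted(digests)}
            for digest in sorted(rois):
                pid = by_digest.get(digest)
                if pid is None:
                    continue
                roi = rois[digest]
                findings = derive_person_findings(
                    node.store, pid, node.rules, start=roi.start, end=roi.end
                )
                intermediate = abstract_findings(findings, node.hypernym_map, digest)
                subgraph = build_online_subgraph(
                    digest=digest,
                    salt_id=self.salt_id,
                    findings=intermediate,
                    visit_dates=[v.visit_date for v in node.store.visits_of(pid)],
                    series_number=self.series_number,
                    origin_hospital_id=node.hospital_id,
                    allowed_hypernyms=node.hypernym_map.allowed_hypernyms,
                    stage="reasoning",
                )
                self.ledger.append(serialize_subgraph(subgraph).decode("utf-8"))

    # -- step 5: summarization -----------------------------------------
    def summarize(self) -> dict:
        subgraphs, eligible, excluded, rois = self._collect()
        sponsor = self._node(self.sponsor_id)
        rules = sponsor.rules
        sponsor_digests = self._digests(sponsor)
        uri_digests = {
            resource_uri(sponsor.hospital_id, "person", pid): h
            for pid, h in sponsor_digests.items()
        }
        local_by_digest = {h.digest: pid for pid, h in sponsor_digests.items()}

        # sponsor-local rule provenance for trail annotation
        local_rules: dict[tuple[str, dt.date, str, bool], str] = {}
        for pid in sorted(sponsor.store.persons):
            for f in derive_person_findings(sponsor.store, pid, rules):
                hyp = sponsor.hypernym_map.hypernym_for(f.concept_id)
                if hyp is not None and f.rule_id is not None:
                    local_rules.setdefault(
                        (local_by_digest[pid] if pid in local_by_digest else pid,
                         f.date, hyp, f.positive),
                        f.rule_id,
                    )

        results: dict[str, CDSResult] = {}
        for digest in sorted(eligible - excluded):
            pathway = merge_remote(
                None, [s for s in subgraphs if s.digest == digest], digest=digest
            )
            local_uri = (
                resource_uri(self.sponsor_id, "person", local_by_digest[digest])
                if digest in local_by_digest
                else None
            )
            roi = rois.get(digest)
            kidney = [
                _PathObs(o, d, c, p)
                for (o, d, c, p) in pathway.findings
                if c == rules.kidney_hypernym
            ]
            verdict = detect_ckd_criteria(kidney, rules.window_days)
            if roi is None or not verdict.met:
                results[digest] = CDSResult(
                    digest=digest,
                    local_person_uri=local_uri,
                    ckd_met=False,
                    first_met_date=None,
                    group=GROUP_NONE,
                    roi=None,
                    visits=pathway.visits,
                )
                continue

            origins = sorted({o for (o, _, _, _) in pathway.findings})
            hospitals_met = {}
            for origin in origins:
                v = detect_ckd_criteria(
                    [o for o in kidney if o.origin == origin], rules.window_days
                )
                if v.met:
                    hospitals_met[origin] = v.first_met_date

            group = GROUP_MULTICENTER
            transfer_date = None
            satisfying = None
            if hospitals_met:
                satisfying = min(hospitals_met, key=lambda h: (hospitals_met[h], h))
                d_star = hospitals_met[satisfying]
                later_elsewhere = sorted(
                    d for (o, d) in pathway.visits if o != satisfying and d > d_star
                )
                if later_elsewhere:
                    group = GROUP_TRANSFERRED
                    transfer_date = later_elsewhere[0]
                else:
                    group = GROUP_SINGLE_CENTER

            risks = tuple(
                RiskEvidence(concept_id=c, date=d, origin=o)
                for (o, d, c, p) in pathway.findings
                if p and c in rules.risk_hypernyms and roi.contains(d)
            )
            pair_dates = set()
            if verdict.supporting_pair:
                pair_dates = {f.date for f in verdict.supporting_pair}
            trail = []
            for (o, d, c, p) in pathway.findings:
                if c != rules.kidney_hypernym and not (
                    p and c in rules.risk_hypernyms and roi.contains(d)
                ):
                    continue
                trail.append(
                    TrailEntry(
                        date=d,
                        concept_id=c,
                        positive=p,
                        origin=o,
                        rule_id=local_rules.get((digest, d, c, p))
                        if o == self.sponsor_id
                        else None,
                        role="chronicity_pair"
                        if (c == rules.kidney_hypernym and p and d in pair_dates)
                        else "evidence",
                    )
                )
            trail.sort(key=lambda t: (t.date, t.concept_id, t.origin))
            results[digest] = CDSResult(
                digest=digest,
                local_person_uri=local_uri,
                ckd_met=True,
                first_met_date=verdict.first_met_date,
                group=group,
                roi=roi,
                risks=tuple(
                    sorted(risks, key=lambda r: (r.date, r.concept_id, r.origin))
                ),
                evidence_trail=tuple(trail),
                visits=pathway.visits,
                transfer_date=transfer_date,
                satisfying_hospital=satisfying,
            )

        alignment = align_patients(
            uri_digests,
            [s for s in subgraphs if s.origin_hospital_id != self.sponsor_id],
            self.sponsor_id,
        )
        return {"results": results, "alignment": alignment, "excluded": frozenset(excluded)}

    def _node(self, hospital_id: str) -> Node:
        for n in self.nodes:
            if n.hospital_id == hospital_id:
                return n
        raise ProtocolError(f"unknown node {hospital_id!r}")

    # -- full run ------------------------------------------------------
    def run(self) -> RunResult:
        eligibility = self.run_initiation_round()
        rois = self.designate_roi()
        self.local_reasoning_round(rois)
        summary = self.summarize()
        receipts = broadcast(
            self.ledger,
            [n.hospital_id for n in self.nodes],
            self.series_number,
        )
        return RunResult(
            sponsor_id=self.sponsor_id,
            series_number=self.series_number,
            results=summary["results"],
            ledger=self.ledger,
            receipts=receipts,
            alignment=summary["alignment"],
            eligibility=eligibility,
            rois=rois,
            excluded_digests=summary["excluded"],
        )


# -- timeline export ---------------------------------------------------


def export_timeline(result: CDSResult, sponsor_id: str) -> dict:
    """JSON timeline document for visualization, schema-validated."""
    by_date: dict[tuple[dt.date, str], list] = {}
    for (origin, date) in result.visits:
        by_date.setdefault((date, origin), [])
    for t in result.evidence_trail:
        by_date.setdefault((t.date, t.origin), []).append(t)
    timeline = []
    for (date, origin) in sorted(by_date):
        timeline.append(
            {
                "date": date.isoformat(),
                "origin": origin,
                "origin_class": "local" if origin == sponsor_id else "remote",
                "findings": [
                    {
                        "concept": t.concept_id,
                        "positive": t.positive,
                        "rule": t.rule_id,
                        "role": t.role,
                    }
                    for t in by_date[(date, origin)]
                ],
            }
        )
    doc = {
        "schema": "fedkg.timeline/1",
        "patient": result.digest,
        "ckd_met": result.ckd_met,
        "group": result.group,
        "roi": (
            {"start": result.roi.start.isoformat(), "end": result.roi.end.isoformat()}
            if result.roi
            else None
        ),
        "first_met_date": result.first_met_date.isoformat()
        if result.first_met_date
        else None,
        "transfer_date": result.transfer_date.isoformat()
        if result.transfer_date
        else None,
        "risks": [
            {"concept": r.concept_id, "date": r.date.isoformat(), "origin": r.origin}
            for r in result.risks
        ],
        "timeline": timeline,
    }
    validate_timeline(doc)
    return doc


_TIMELINE_KEYS = {
    "schema", "patient", "ckd_met", "group", "roi", "first_met_date",
    "transfer_date", "risks", "timeline",
}


def validate_timeline(doc: dict) -> None:
    if set(doc) != _TIMELINE_KEYS:
        raise SchemaError(f"timeline keys mismatch: {sorted(set(doc) ^ _TIMELINE_KEYS)}")
    if doc["schema"] != "fedkg.timeline/1":
        raise SchemaError("unknown schema tag")
    if doc["group"] not in {
        GROUP_MULTICENTER, GROUP_TRANSFERRED, GROUP_SINGLE_CENTER, GROUP_NONE,
    }:
        raise SchemaError(f"unknown group {doc['group']!r}")
    if doc["ckd_met"] and doc["roi"] is None:
        raise SchemaError("ckd_met without an ROI block")
    if not doc["ckd_met"] and doc["roi"] is not None:
        raise SchemaError("ROI block on a negative result")
    if doc["roi"] is not None:
        if parse_date(doc["roi"]["start"]) > parse_date(doc["roi"]["end"]):
            raise SchemaError("ROI start after end")
    for entry in doc["timeline"]:
        if set(entry) != {"date", "origin", "origin_class", "findings"}:
            raise SchemaError("bad timeline entry keys")
        if entry["origin_class"] not in {"local", "remote"}:
            raise SchemaError("bad origin_class")
        parse_date(entry["date"])
    for r in doc["risks"]:
        parse_date(r["date"])


# -- secure two-party comparison interface -----------------------------


class SecureComparisonChannel:
    """Ordering of two privately held values without value disclosure.

    Nodes register values under opaque references; ``compare`` reveals only
    the ordering symbol.  This is the plaintext trusted-evaluator reference
    implementation of the interface; a cryptographic two-party comparison
    backend can be substituted behind the same two calls.
    """

    def __init__(self):
        self._values: dict[tuple[str, str], float] = {}

    def register(self, node_id: str, ref: str, value: float) -> None:
        self._values[(node_id, ref)] = float(value)

    def compare(self, ref_a: tuple[str, str], ref_b: tuple[str, str]) -> str:
        try:
            a = self._values[ref_a]
            b = self._values[ref_b]
        except KeyError as exc:
            raise LookupError(f"unknown value reference {exc.args[0]!r}") from None
        if a < b:
            return "<"
        if a > b:
            return ">"
        return "="
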