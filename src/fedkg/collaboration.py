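"""Online subgraphs, their canonical wire format, and the synchronization ledger.

The online subgraph is the only structure that crosses hospital boundaries:
a hashed patient identity, virtual visit nodes carrying dates only, and
virtual finding nodes carrying a hypernym concept and a positive/negative
label.  No raw identity, no measurement values or units, no leaf concepts,
no department names, no provenance.  Serialization is canonical JSON so two
serializations of the same subgraph are byte-identical, and the
deserializer re-validates the privacy contract by rejecting any payload
with unexpected fields.

The blockchain network of the deployed system is simulated here as a
single-sequencer SHA-256 hash chain with synchronous broadcast: ordered,
tamper-evident, traceable delivery with per-node receipts and an optional
per-message recipient allow-list standing in for attribute-based access
control.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from ._util import canonical_json, parse_date, sha256_hex
from .local_reasoning import IntermediateFinding


class PrivacyViolationError(ValueError):
    """A value-bearing or leaf-level element tried to cross the boundary."""


class TamperError(RuntimeError):
    def __init__(self, first_bad_index: int):
        super().__init__(f"ledger verification failed at block {first_bad_index}")
        self.first_bad_index = first_bad_index


@dataclass(frozen=True)
class VirtualFinding:
    date: dt.date
    concept_id: str  # must be a designated hypernym
    positive: bool


@dataclass(frozen=True)
class OnlineSubgraph:
    origin_hospital_id: str
    series_number: int
    stage: str  # "initiation" | "reasoning"
    digest: str
    salt_id: str
    visit_dates: tuple[dt.date, ...] = ()
    findings: tuple[VirtualFinding, ...] = ()

    @property
    def node_count(self) -> int:
        # 1 patient node + one virtual visit per date + one node per finding
        return 1 + len(self.visit_dates) + len(self.findings)

    @property
    def edge_count(self) -> int:
        # patient->visit per date, visit->finding per finding
        return len(self.visit_dates) + len(self.findings)


def build_online_subgraph(
    digest: str,
    salt_id: str,
    findings: Iterable[IntermediateFinding],
    visit_dates: Iterable[dt.date],
    series_number: int,
    origin_hospital_id: str,
    allowed_hypernyms: Iterable[str],
    stage: str = "initiation",
) -> OnlineSubgraph:
    """Assemble the minimal exchange graph for one patient.

    Every finding must carry a whitelisted hypernym concept; anything else
    is a hard privacy violation.  One virtual visit node per distinct date
    that either bears a finding or is explicitly flagged as a qualifying
    visit date.
    """
    allowed = frozenset(allowed_hypernyms)
    vfindings: list[VirtualFinding] = []
    for f in findings:
        for forbidden in ("value", "unit", "provenance", "identity"):
            if getattr(f, forbidden, None) is not None:
                raise PrivacyViolationError(
                    f"finding carries forbidden field {forbidden!r}"
                )
        if f.hypernym_concept_id not in allowed:
            raise PrivacyViolationError(
                f"concept {f.hypernym_concept_id!r} is not a designated hypernym"
            )
        vfindings.append(
            VirtualFinding(
                date=f.date, concept_id=f.hypernym_concept_id, positive=f.positive
            )
        )
    vfindings.sort(key=lambda v: (v.date, v.concept_id, v.positive))
    dates = sorted(set(visit_dates) | {v.date for v in vfindings})
    return OnlineSubgraph(
        origin_hospital_id=origin_hospital_id,
        series_number=int(series_number),
        stage=stage,
        digest=digest,
        salt_id=salt_id,
        visit_dates=tuple(dates),
        findings=tuple(vfindings),
    )


# -- canonical wire format --------------------------------------------

_TOP_KEYS = {
    "type", "origin", "series", "stage", "patient", "visits", "findings",
}
_PATIENT_KEYS = {"digest", "salt_id"}
_VISIT_KEYS = {"date"}
_FINDING_KEYS = {"date", "concept", "positive"}


def subgraph_to_dict(g: OnlineSubgraph) -> dict:
    return {
        "type": "subgraph",
        "origin": g.origin_hospital_id,
        "series": g.series_number,
        "stage": g.stage,
        "patient": {"digest": g.digest, "salt_id": g.salt_id},
        "visits": [{"date": d.isoformat()} for d in g.visit_dates],
        "findings": [
            {"date": f.date.isoformat(), "concept": f.concept_id, "positive": f.positive}
            for f in g.findings
        ],
    }


def serialize_subgraph(g: OnlineSubgraph) -> bytes:
    """Canonical JSON bytes: sorted keys, sorted node lists."""
    return canonical_json(subgraph_to_dict(g)).encode("utf-8")


def _require_keys(obj: dict, allowed: set[str], where: str) -> None:
    extra = set(obj) - allowed
    if extra:
        raise PrivacyViolationError(f"forbidden field(s) {sorted(extra)} in {where}")


def deserialize_subgraph(
    payload: bytes | str, allowed_hypernyms: Optional[Iterable[str]] = None
) -> OnlineSubgraph:
    """Parse and re-validate a subgraph payload.

    Any unexpected field anywhere in the document (for example an injected
    ``value``) is rejected as a privacy violation, as is any finding concept
    outside the hypernym whitelist when one is supplied.
    """
    if isinstance(payload, bytes):
        payload = payload.decode("utf-8")
    doc = json.loads(payload)
    if not isinstance(doc, dict) or doc.get("type") != "subgraph":
        raise PrivacyViolationError("payload is not an online subgraph")
    _require_keys(doc, _TOP_KEYS, "subgraph")
    _require_keys(doc["patient"], _PATIENT_KEYS, "patient node")
    for v in doc.get("visits", []):
        _require_keys(v, _VISIT_KEYS, "virtual visit node")
    allowed = frozenset(allowed_hypernyms) if allowed_hypernyms is not None else None
    findings = []
    for f in doc.get("findings", []):
        _require_keys(f, _FINDING_KEYS, "virtual finding node")
        if allowed is not None and f["concept"] not in allowed:
            raise PrivacyViolationError(
                f"concept {f['concept']!r} is not a designated hypernym"
            )
        findings.append(
            VirtualFinding(
                date=parse_date(f["date"]),
                concept_id=f["concept"],
                positive=bool(f["positive"]),
            )
        )
    return OnlineSubgraph(
        origin_hospital_id=doc["origin"],
        series_number=int(doc["series"]),
        stage=doc["stage"],
        digest=doc["patient"]["digest"],
        salt_id=doc["patient"]["salt_id"],
        visit_dates=tuple(parse_date(v["date"]) for v in doc.get("visits", [])),
        findings=tuple(findings),
    )


# -- hash-chained ledger ----------------------------------------------

GENESIS_PREV_HASH = "0" * 64


def _block_hash(index: int, prev_hash: str, payload_hash: str) -> str:
    return sha256_hex(f"{index}|{prev_hash}|{payload_hash}")


@dataclass(frozen=True)
class LedgerBlock:
    index: int
    prev_hash: str
    payload: str
    payload_hash: str
    block_hash: str


@dataclass
class Ledger:
    """Append-only hash chain; every append verifies the chain first."""

    blocks: list[LedgerBlock] = field(default_factory=list)

    def append(self, payload: str) -> LedgerBlock:
        self.verify_or_raise()
        index = len(self.blocks)
        prev = self.blocks[-1].block_hash if self.blocks else GENESIS_PREV_HASH
        payload_hash = sha256_hex(payload)
        block = LedgerBlock(
            index=index,
            prev_hash=prev,
            payload=payload,
            payload_hash=payload_hash,
            block_hash=_block_hash(index, prev, payload_hash),
        )
        self.blocks.append(block)
        return block

    def verify(self) -> tuple[bool, Optional[int]]:
        """Recompute every hash; return (ok, first bad block index)."""
        prev = GENESIS_PREV_HASH
        for i, b in enumerate(self.blocks):
            if (
                b.index != i
                or b.prev_hash != prev
                or b.payload_hash != sha256_hex(b.payload)
                or b.block_hash != _block_hash(b.index, b.prev_hash, b.payload_hash)
            ):
                return False, i
            prev = b.block_hash
        return True, None

    def verify_or_raise(self) -> None:
        ok, bad = self.verify()
        if not ok:
            raise TamperError(bad)

    def payloads(self) -> list[str]:
        return [b.payload for b in self.blocks]

    # -- persistence (JSON lines, one block per line) -----------------
    def to_jsonl(self) -> str:
        return "".join(
            canonical_json(
                {
                    "index": b.index,
                    "prev_hash": b.prev_hash,
                    "payload": b.payload,
                    "payload_hash": b.payload_hash,
                    "block_hash": b.block_hash,
                }
            )
            + "\n"
            for b in self.blocks
        )

    @classmethod
    def from_jsonl(cls, text: str) -> "Ledger":
        blocks = []
        for line in text.splitlines():
            if not line.strip():
                continue
            d = json.loads(line)
            blocks.append(
                LedgerBlock(
                    index=int(d["index"]),
                    prev_hash=d["prev_hash"],
                    payload=d["payload"],
                    payload_hash=d["payload_hash"],
                    block_hash=d["block_hash"],
                )
            )
        ledger = cls(blocks=blocks)
        ledger.verify_or_raise()
        return ledger


@dataclass(frozen=True)
class Receipt:
    node_id: str
    series_number: int
    first_index: int
    last_index: int
    last_block_hash: str


def broadcast(
    ledger: Ledger,
    nodes: Sequence[str],
    series_number: int,
    since_index: int = 0,
    allow_list: Optional[dict[int, frozenset[str]]] = None,
) -> tuple[Receipt, ...]:
    """Deliver the verified chain suffix to every registered node.

    ``allow_list`` optionally restricts individual blocks to named
    recipients (the access-policy stand-in for payload encryption); a block
    outside a node's allowance is simply not delivered to it.  Returns one
    receipt per node recording what it received.
    """
    ledger.verify_or_raise()
    receipts = []
    suffix = ledger.blocks[since_index:]
    for node in sorted(nodes):
        delivered = [
            b
            for b in suffix
            if allow_list is None
            or b.index not in allow_list
            or node in allow_list[b.index]
        ]
        if delivered:
            receipts.append(
                Receipt(
                    node_id=node,
                    series_number=series_number,
                    first_index=delivered[0].index,
                    last_index=delivered[-1].index,
                    last_block_hash=delivered[-1].block_hash,
                )
            )
        else:
            receipts.append(
                Receipt(
                    node_id=node,
                    series_number=series_number,
                    first_index=-1,
                    last_index=-1,
                    last_block_hash="",
                )
            )
    return tuple(receipts)


# -- merged patient pathway -------------------------------------------


@dataclass(frozen=True)
class MergedPathway:
    """Origin-tagged union of local and virtual visits/findings for one patient.

    Deduplication key for virtual nodes: (origin hospital, date, concept,
    label), which makes merging idempotent.
    """

    digest: str
    visits: tuple[tuple[str, dt.date], ...] = ()  # (origin, date)
    findings: tuple[tuple[str, dt.date, str, bool], ...] = ()

    def visit_dates(self) -> tuple[dt.date, ...]:
        return tuple(sorted({d for _, d in self.visits}))


def merge_remote(
    pathway: Optional[MergedPathway],
    subgraphs: Iterable[OnlineSubgraph],
    digest: Optional[str] = None,
) -> MergedPathway:
    """Merge incoming subgraphs into a patient's pathway (idempotent).

    ``pathway`` may be None to start from the patient's empty pathway;
    subgraphs whose digest differs from the pathway's are ignored (logged
    by the caller if desired).  Merged timeline = existing visits plus
    distinct new virtual visits, sorted by date then origin.
    """
    if pathway is None:
        if digest is None:
            raise ValueError("digest required when starting a fresh pathway")
        pathway = MergedPathway(digest=digest)
    visits = set(pathway.visits)
    findings = set(pathway.findings)
    for sg in subgraphs:
        if sg.digest != pathway.digest:
            continue
        for d in sg.visit_dates:
            visits.add((sg.origin_hospital_id, d))
        for f in sg.findings:
            findings.add((sg.origin_hospital_id, f.date, f.concept_id, f.positive))
    return MergedPathway(
        digest=pathway.digest,
        visits=tuple(sorted(visits, key=lambda t: (t[1], t[0]))),
        findings=tuple(sorted(findings, key=lambda t: (t[1], t[0], t[2], t[3]))),
    )
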