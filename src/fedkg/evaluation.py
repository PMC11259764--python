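"""Evaluation quantities: lead time, risk coverage, duplicate-exam reduction,
and detection quality against synthetic ground truth.

Discovery lead time measures how much earlier collaborative reasoning meets
the chronicity criteria than a single-hospital assessment would diagnose:
for the multicenter-data group it is t_diagnosis - t_CDS (criteria-met date),
for the transferred group t_diagnosis - t_transfer (first post-transfer
visit).  Risk coverage compares the risk set surfaced by collaborative
reasoning inside a 3-month window at the ROI against the risk set derivable
from the sponsor's own store over its latest 3 months, reported in percent.
Duplicate-exam reduction counts kidney-function tests already available at
other hospitals inside the ROI that the sponsor would otherwise re-order.

On synthetic data t_diagnosis comes from the generator's ground truth; the
original study's clinician-assessed values are not reproduction targets.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .alignment import hash_identity
from .local_reasoning import derive_person_findings, detect_ckd_criteria
from .protocol import (
    GROUP_MULTICENTER,
    GROUP_NONE,
    GROUP_TRANSFERRED,
    CDSResult,
    Node,
)
from .synthetic_cohort import GroundTruth


@dataclass(frozen=True)
class LeadTimeRecord:
    digest: str
    group: str
    t_cds: Optional[dt.date]
    t_diagnosis: dt.date
    t_transfer: Optional[dt.date]
    lead_days: int


def lead_time(result: CDSResult, truth: GroundTruth) -> Optional[LeadTimeRecord]:
    """Per-patient discovery lead time; None when no diagnosis date exists."""
    if not result.ckd_met or truth.diagnosis_date is None:
        return None
    if result.group == GROUP_TRANSFERRED:
        t_transfer = result.transfer_date or truth.transfer_date
        if t_transfer is None:
            return None
        lead = (truth.diagnosis_date - t_transfer).days
    else:
        lead = (truth.diagnosis_date - result.first_met_date).days
    return LeadTimeRecord(
        digest=result.digest,
        group=result.group,
        t_cds=result.first_met_date,
        t_diagnosis=truth.diagnosis_date,
        t_transfer=result.transfer_date,
        lead_days=lead,
    )


def aggregate_lead_times(records: Sequence[LeadTimeRecord]) -> dict:
    out: dict[str, dict] = {}
    for group in sorted({r.group for r in records}):
        days = np.array([r.lead_days for r in records if r.group == group], dtype=float)
        out[group] = {
            "n": int(days.size),
            "mean": float(days.mean()),
            "sd": float(days.std(ddof=1)) if days.size > 1 else 0.0,
            "median": float(np.median(days)),
        }
    return out


@dataclass(frozen=True)
class CoverageRecord:
    digest: str
    risks_multicenter: frozenset[str]
    risks_single: frozenset[str]
    cov_percent: Optional[float]  # None when the single-hospital baseline is empty


def risk_coverage(
    result: CDSResult, sponsor_node: Node, window_days: int = 90
) -> CoverageRecord:
    """Collaborative vs sponsor-only risk sets over 3-month windows.

    The collaborative window anchors at the ROI end (most recent evidence);
    the baseline window is the sponsor store's latest ``window_days`` ending
    at the patient's last sponsor visit.
    """
    if result.roi is None:
        raise ValueError("risk coverage needs a detected patient with an ROI")
    lo = result.roi.end - dt.timedelta(days=window_days)
    multi = frozenset(
        r.concept_id for r in result.risks if lo <= r.date <= result.roi.end
    )

    single: frozenset[str] = frozenset()
    if result.local_person_uri is not None:
        pid = result.local_person_uri.rsplit("/", 1)[-1]
        visits = sponsor_node.store.visits_of(pid)
        if visits:
            latest = max(v.visit_date for v in visits)
            start = latest - dt.timedelta(days=window_days)
            findings = derive_person_findings(
                sponsor_node.store, pid, sponsor_node.rules, start=start, end=latest
            )
            hyps = set()
            for f in findings:
                if not f.positive:
                    continue
                hyp = sponsor_node.hypernym_map.hypernym_for(f.concept_id)
                if hyp in sponsor_node.rules.risk_hypernyms:
                    hyps.add(hyp)
            single = frozenset(hyps)
    cov = 100.0 * len(multi) / len(single) if single else None
    return CoverageRecord(
        digest=result.digest,
        risks_multicenter=multi,
        risks_single=single,
        cov_percent=cov,
    )


def aggregate_coverage(records: Sequence[CoverageRecord], mode: str = "per_patient") -> Optional[float]:
    """Mean of per-patient ratios (default) or pooled-count ratio, percent."""
    if mode == "per_patient":
        ratios = [r.cov_percent for r in records if r.cov_percent is not None]
        return float(np.mean(ratios)) if ratios else None
    if mode == "pooled":
        multi = sum(len(r.risks_multicenter) for r in records if r.risks_single)
        single = sum(len(r.risks_single) for r in records)
        return 100.0 * multi / single if single else None
    raise ValueError(f"unknown mode {mode!r}")


@dataclass(frozen=True)
class DuplicateExamRecord:
    digest: str
    avoided_tests: int


def duplicate_exam_reduction(
    result: CDSResult,
    nodes: Sequence[Node],
    sponsor_id: str,
    salt: str,
    salt_id: str = "consortium",
    mirror_window_days: int = 14,
) -> DuplicateExamRecord:
    """Remote kidney tests inside the ROI not mirrored sponsor-side.

    A remote test is mirrored when the sponsor holds a kidney-function test
    for the same patient within +/- ``mirror_window_days`` of it; unmirrored
    remote tests are ones a single-hospital assessment would re-order.  The
    consortium salt re-derives digests to locate the patient at each node.
    """
    if result.roi is None:
        raise ValueError("duplicate-exam reduction needs a detected patient")
    sponsor = next(n for n in nodes if n.hospital_id == sponsor_id)
    sponsor_dates: list[dt.date] = []
    spid = (
        result.local_person_uri.rsplit("/", 1)[-1]
        if result.local_person_uri is not None
        else None
    )
    if spid is not None:
        for e in sponsor.store.events.values():
            if (
                e.kind == "measurement"
                and e.concept_id in sponsor.rules.kidney_measurements
                and sponsor.store.visits[e.visit_id].person_id == spid
            ):
                sponsor_dates.append(e.event_date)
    avoided = 0
    for node in nodes:
        if node.hospital_id == sponsor_id:
            continue
        for pid in sorted(node.store.persons):
            digest = hash_identity(
                node.store.persons[pid].identity, salt, salt_id
            ).digest
            if digest != result.digest:
                continue
            for e in node.store.events.values():
                if (
                    e.kind == "measurement"
                    and e.concept_id in node.rules.kidney_measurements
                    and node.store.visits[e.visit_id].person_id == pid
                    and result.roi.contains(e.event_date)
                ):
                    mirrored = any(
                        abs((e.event_date - d).days) <= mirror_window_days
                        for d in sponsor_dates
                    )
                    if not mirrored:
                        avoided += 1
    return DuplicateExamRecord(digest=result.digest, avoided_tests=avoided)


def single_store_verdict(node: Node, person_id: str):
    """Chronicity verdict from one hospital's store alone."""
    findings = derive_person_findings(node.store, person_id, node.rules)
    kidney = [
        f for f in findings if f.concept_id in node.rules.abnormal_kidney_findings
    ]
    return detect_ckd_criteria(kidney, node.rules.window_days)


def detection_metrics(
    results: dict, truths: Sequence[GroundTruth], salt: str,
    salt_id: str = "consortium",
) -> dict:
    """Confusion summary per planted phenotype.

    Sensitivity over planted positives, specificity over controls and
    recovery confounders (the recovery group is also reported separately,
    mirroring the false-positive analysis attributed to kidney-function
    recovery), decoy leakage, and group-label accuracy.
    """
    by_digest = {}
    for t in truths:
        by_digest[hash_identity(t.identity, salt, salt_id).digest] = t

    counts = {p: {"n": 0, "flagged": 0, "correct_group": 0} for p in
              ("multicenter_ckd", "transferred_ckd", "recovery_confounder",
               "control", "excluded_decoy")}
    expected_group = {
        "multicenter_ckd": GROUP_MULTICENTER,
        "transferred_ckd": GROUP_TRANSFERRED,
    }
    for digest, truth in by_digest.items():
        c = counts[truth.phenotype]
        c["n"] += 1
        result = results.get(digest)
        flagged = result is not None and result.ckd_met
        if flagged:
            c["flagged"] += 1
            if truth.phenotype in expected_group and result.group == expected_group[
                truth.phenotype
            ]:
                c["correct_group"] += 1

    def rate(num, den):
        return float(num) / den if den else None

    positives = counts["multicenter_ckd"]["n"] + counts["transferred_ckd"]["n"]
    flagged_pos = counts["multicenter_ckd"]["flagged"] + counts["transferred_ckd"]["flagged"]
    correct = counts["multicenter_ckd"]["correct_group"] + counts["transferred_ckd"]["correct_group"]
    negatives = counts["control"]["n"] + counts["recovery_confounder"]["n"]
    false_pos = counts["control"]["flagged"] + counts["recovery_confounder"]["flagged"]
    return {
        "by_phenotype": counts,
        "sensitivity": rate(flagged_pos, positives),
        "sensitivity_multicenter": rate(
            counts["multicenter_ckd"]["flagged"], counts["multicenter_ckd"]["n"]
        ),
        "sensitivity_transferred": rate(
            counts["transferred_ckd"]["flagged"], counts["transferred_ckd"]["n"]
        ),
        "group_accuracy": rate(correct, flagged_pos),
        "specificity": rate(negatives - false_pos, negatives),
        "recovery_not_met_rate": rate(
            counts["recovery_confounder"]["n"] - counts["recovery_confounder"]["flagged"],
            counts["recovery_confounder"]["n"],
        ),
        "controls_flagged": counts["control"]["flagged"],
        "decoys_flagged": counts["excluded_decoy"]["flagged"],
        "ppv": rate(flagged_pos, flagged_pos + false_pos + counts["excluded_decoy"]["flagged"]),
    }
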