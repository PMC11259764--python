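import datetime as dt
import statistics

import pytest

from fedkg.alignment import hash_identity
from fedkg.ehr_store import EHRStore, EventRecord, PersonRecord, VisitRecord
from fedkg.evaluation import (
    CoverageRecord,
    aggregate_coverage,
    aggregate_lead_times,
    detection_metrics,
    duplicate_exam_reduction,
    lead_time,
    risk_coverage,
    single_store_verdict,
)
from fedkg.protocol import (
    GROUP_MULTICENTER,
    GROUP_TRANSFERRED,
    CDSResult,
    Node,
    RiskEvidence,
    ROI,
)
from fedkg.synthetic_cohort import GroundTruth

from conftest import SALT, date

DIGEST = "d" * 64


def _result(group, first_met, roi=None, transfer=None, risks=(), local_uri=None):
    return CDSResult(
        digest=DIGEST,
        local_person_uri=local_uri,
        ckd_met=True,
        first_met_date=first_met,
        group=group,
        roi=roi,
        risks=risks,
        transfer_date=transfer,
    )


def _truth(diagnosis, transfer=None, phenotype="multicenter_ckd"):
    return GroundTruth(
        identity="330100195001011234",
        phenotype=phenotype,
        diagnosis_date=diagnosis,
        transfer_date=transfer,
    )


class TestLeadTime:
    def test_multicenter_lead_is_diagnosis_minus_cds(self):
        rec = lead_time(
            _result(GROUP_MULTICENTER, date("2019-08-02")),
            _truth(date("2020-08-01")),
        )
        assert rec.lead_days == 365

    def test_transferred_lead_is_diagnosis_minus_transfer(self):
        rec = lead_time(
            _result(GROUP_TRANSFERRED, date("2019-06-01"),
                    transfer=date("2020-01-10")),
            _truth(date("2020-05-10"), phenotype="transferred_ckd"),
        )
        assert rec.lead_days == 121

    def test_missing_diagnosis_date_skipped(self):
        assert lead_time(_result(GROUP_MULTICENTER, date("2019-08-02")),
                         _truth(None)) is None

    def test_aggregate_matches_independent_recomputation(self):
        leads = [
            lead_time(_result(GROUP_MULTICENTER, date("2019-01-01")),
                      _truth(date("2019-01-01") + dt.timedelta(days=d)))
            for d in (100, 250, 431)
        ]
        agg = aggregate_lead_times(leads)[GROUP_MULTICENTER]
        assert agg["n"] == 3
        assert agg["mean"] == pytest.approx(statistics.mean([100, 250, 431]))
        assert agg["sd"] == pytest.approx(statistics.stdev([100, 250, 431]))
        assert agg["median"] == pytest.approx(statistics.median([100, 250, 431]))


def _sponsor_node(vocab, hmap, rules, events):
    store = EHRStore(hospital_id="H1")
    store.persons["p1"] = PersonRecord("p1", "330100195001011234", 1950, "male")
    for i, (d, kind, concept, value, unit) in enumerate(events, start=1):
        vid = f"v{i}"
        store.visits[vid] = VisitRecord(vid, "p1", "H1", d, "cardiology")
        store.events[f"e{i}"] = EventRecord(
            f"e{i}", vid, kind, concept, value, unit, d
        )
    return Node("H1", store.validate(), vocab, hmap, rules)


class TestRiskCoverage:
    def test_four_vs_three_risks_is_133_percent(self, vocab, hmap, rules):
        """Collaborative {AKI, BUN, UA, UP} vs sponsor-only {BUN, UA, UP}."""
        end = date("2020-06-01")
        roi = ROI(digest=DIGEST, start=date("2020-01-01"), end=end)
        risks = tuple(
            RiskEvidence(c, end - dt.timedelta(days=10), "H2")
            for c in ("aki_history", "elevated_bun", "elevated_uric_acid",
                      "urinary_protein")
        )
        node = _sponsor_node(vocab, hmap, rules, [
            (end - dt.timedelta(days=5), "measurement", "bun_measurement", 12.0, "mmol/L"),
            (end - dt.timedelta(days=5), "measurement", "uric_acid_measurement", 500.0, "µmol/L"),
            (end - dt.timedelta(days=3), "diagnosis", "proteinuria_dx", None, None),
        ])
        record = risk_coverage(
            _result(GROUP_MULTICENTER, end, roi=roi, risks=risks,
                    local_uri="H1/person/p1"),
            node,
        )
        assert record.risks_single == {
            "elevated_bun", "elevated_uric_acid", "urinary_protein",
        }
        assert record.cov_percent == pytest.approx(100 * 4 / 3)
        assert round(record.cov_percent) == 133

    def test_identical_sets_give_100(self):
        rec = CoverageRecord(DIGEST, frozenset({"a", "b"}), frozenset({"a", "b"}),
                             100.0)
        assert aggregate_coverage([rec]) == pytest.approx(100.0)

    def test_empty_baseline_excluded_from_mean(self):
        records = [
            CoverageRecord(DIGEST, frozenset({"a"}), frozenset(), None),
            CoverageRecord(DIGEST, frozenset({"a", "b"}), frozenset({"a"}), 200.0),
        ]
        assert aggregate_coverage(records) == pytest.approx(200.0)

    def test_pooled_mode(self):
        records = [
            CoverageRecord(DIGEST, frozenset({"a", "b"}), frozenset({"a"}), 200.0),
            CoverageRecord(DIGEST, frozenset({"a"}), frozenset({"a"}), 100.0),
        ]
        assert aggregate_coverage(records, mode="pooled") == pytest.approx(150.0)


class TestDuplicateExamReduction:
    def _nodes(self, vocab, hmap, rules, remote_days, sponsor_days):
        sponsor = _sponsor_node(vocab, hmap, rules, [
            (d, "measurement", "egfr_measurement", 50.0, "mL/min")
            for d in sponsor_days
        ])
        remote_store = EHRStore(hospital_id="H2")
        remote_store.persons["p9"] = PersonRecord(
            "p9", "330100195001011234", 1950, "male"
        )
        for i, d in enumerate(remote_days, start=1):
            vid = f"rv{i}"
            remote_store.visits[vid] = VisitRecord(vid, "p9", "H2", d, "urology")
            remote_store.events[f"re{i}"] = EventRecord(
                f"re{i}", vid, "measurement", "egfr_measurement", 48.0, "mL/min", d
            )
        remote = Node("H2", remote_store.validate(), vocab, hmap, rules)
        return [sponsor, remote]

    def test_unmirrored_remote_tests_counted(self, vocab, hmap, rules):
        roi = ROI(digest=None or "d" * 64, start=date("2020-01-01"),
                  end=date("2020-12-01"))
        digest = hash_identity("330100195001011234", SALT).digest
        result = CDSResult(
            digest=digest, local_person_uri="H1/person/p1", ckd_met=True,
            first_met_date=roi.end, group=GROUP_MULTICENTER, roi=roi,
        )
        nodes = self._nodes(
            vocab, hmap, rules,
            remote_days=[date("2020-02-01"), date("2020-05-01"), date("2020-08-01")],
            sponsor_days=[],
        )
        rec = duplicate_exam_reduction(result, nodes, "H1", SALT)
        assert rec.avoided_tests == 3

    def test_mirrored_tests_not_counted(self, vocab, hmap, rules):
        roi = ROI(digest="d" * 64, start=date("2020-01-01"), end=date("2020-12-01"))
        digest = hash_identity("330100195001011234", SALT).digest
        result = CDSResult(
            digest=digest, local_person_uri="H1/person/p1", ckd_met=True,
            first_met_date=roi.end, group=GROUP_MULTICENTER, roi=roi,
        )
        nodes = self._nodes(
            vocab, hmap, rules,
            remote_days=[date("2020-02-01"), date("2020-05-01")],
            sponsor_days=[date("2020-02-10"), date("2020-05-01")],
        )
        rec = duplicate_exam_reduction(result, nodes, "H1", SALT)
        assert rec.avoided_tests == 0

    def test_removing_remote_test_never_increases_count(self, vocab, hmap, rules):
        roi = ROI(digest="d" * 64, start=date("2020-01-01"), end=date("2020-12-01"))
        digest = hash_identity("330100195001011234", SALT).digest
        result = CDSResult(
            digest=digest, local_person_uri="H1/person/p1", ckd_met=True,
            first_met_date=roi.end, group=GROUP_MULTICENTER, roi=roi,
        )
        days = [date("2020-02-01"), date("2020-05-01"), date("2020-08-01")]
        baseline = duplicate_exam_reduction(
            result, self._nodes(vocab, hmap, rules, days, []), "H1", SALT
        ).avoided_tests
        for drop in range(len(days)):
            fewer = days[:drop] + days[drop + 1:]
            count = duplicate_exam_reduction(
                result, self._nodes(vocab, hmap, rules, fewer, []), "H1", SALT
            ).avoided_tests
            assert count <= baseline


class TestDetectionMetrics:
    def test_all_controls_run_perfect_specificity(self, vocab, hmap, rules):
        from fedkg.synthetic_cohort import CohortConfig, generate_consortium
        from conftest import run_consortium

        stores, truths = generate_consortium(
            CohortConfig(
                n_patients=15, seed=21,
                phenotype_fractions={
                    "multicenter_ckd": 0, "transferred_ckd": 0,
                    "recovery_confounder": 0, "control": 1,
                },
                decoy_fraction=0.0,
            )
        )
        _, outcome = run_consortium(stores, vocab, hmap, rules)
        metrics = detection_metrics(outcome.results, truths, SALT)
        assert metrics["specificity"] == 1.0
        assert metrics["controls_flagged"] == 0
        assert sum(r.ckd_met for r in outcome.results.values()) == 0

    def test_full_small_run_metrics(self, small_run):
        _, truths, outcome = small_run
        metrics = detection_metrics(outcome.results, truths, SALT)
        assert metrics["sensitivity"] == 1.0
        assert metrics["group_accuracy"] == 1.0
        assert metrics["recovery_not_met_rate"] == 1.0
        assert metrics["decoys_flagged"] == 0

    def test_single_store_verdict_matches_truth(self, small_run):
        nodes, truths, _ = small_run
        by_id = {n.hospital_id: n for n in nodes}
        for truth in truths:
            if truth.excluded:
                continue
            for h, pid in truth.person_ids.items():
                verdict = single_store_verdict(by_id[h], pid)
                expected = truth.per_hospital_satisfiable.get(h)
                assert verdict.met == (expected is not None)
                if expected is not None:
                    assert verdict.first_met_date == expected
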