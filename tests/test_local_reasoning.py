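import datetime as dt
import random

import pytest
from hypothesis import given, strategies as st

from fedkg.ehr_store import EHRStore, EventRecord, PersonRecord, VisitRecord
from fedkg.local_reasoning import (
    KIDNEY_DIAGNOSIS,
    NEPHROLOGY_VISIT,
    NO_KIDNEY_TEST,
    IntermediateFinding,
    abstract_findings,
    convert_value,
    derive_person_findings,
    derive_visit_findings,
    detect_ckd_criteria,
    initiation_protocol,
    load_rules,
    save_rules,
)

from conftest import date
from oracles import brute_force_chronicity

IDENTITY = "330100195001011234"


def _store(visits):
    """visits: list of (day, department, [(kind, concept, value, unit)])."""
    store = EHRStore(hospital_id="H1")
    store.persons["p1"] = PersonRecord("p1", IDENTITY, 1950, "male")
    for i, (day, dept, events) in enumerate(visits, start=1):
        vid = f"v{i}"
        d = dt.date(2019, 1, 1) + dt.timedelta(days=day)
        store.visits[vid] = VisitRecord(vid, "p1", "H1", d, dept)
        for j, (kind, concept, value, unit) in enumerate(events):
            eid = f"e{i}_{j}"
            store.events[eid] = EventRecord(eid, vid, kind, concept, value, unit, d)
    return store.validate()


def _obs(pairs):
    """(day, positive) tuples to chronicity-rule inputs."""
    base = dt.date(2019, 1, 1)
    return [
        IntermediateFinding("0" * 64, base + dt.timedelta(days=d),
                            "abnormal_kidney_function", p)
        for d, p in pairs
    ]


class TestInitiationProtocol:
    def test_kidney_test_with_cardiology_visits_is_eligible(self, rules):
        store = _store([(0, "cardiology",
                         [("measurement", "egfr_measurement", 55.0, "mL/min")])])
        decision = initiation_protocol(store, "p1", rules)
        assert decision.eligible and decision.reasons == ()

    def test_nephrology_visit_excludes(self, rules):
        store = _store([
            (0, "cardiology", [("measurement", "egfr_measurement", 55.0, "mL/min")]),
            (5, "nephrology", []),
        ])
        decision = initiation_protocol(store, "p1", rules)
        assert not decision.eligible and NEPHROLOGY_VISIT in decision.reasons

    def test_kidney_diagnosis_excludes(self, rules):
        store = _store([
            (0, "cardiology", [
                ("measurement", "egfr_measurement", 55.0, "mL/min"),
                ("diagnosis", "ckd_dx", None, None),
            ]),
        ])
        decision = initiation_protocol(store, "p1", rules)
        assert not decision.eligible and KIDNEY_DIAGNOSIS in decision.reasons

    def test_no_measurement_gives_no_kidney_test_reason(self, rules):
        store = _store([(0, "cardiology", [])])
        decision = initiation_protocol(store, "p1", rules)
        assert not decision.eligible and decision.reasons == (NO_KIDNEY_TEST,)


class TestDeriveVisitFindings:
    def test_low_egfr_fires_positive_finding(self, rules):
        store = _store([(0, "cardiology",
                         [("measurement", "egfr_measurement", 55.0, "mL/min")])])
        (finding,) = derive_visit_findings(
            store.visits["v1"], store.events_of_visit("v1"), rules
        )
        assert finding.concept_id == "decreased_egfr" and finding.positive
        assert finding.provenance == "measurement"

    def test_boundary_egfr_60_is_not_abnormal(self, rules):
        """Strict inequality: a value exactly at the threshold is normal."""
        store = _store([(0, "cardiology",
                         [("measurement", "egfr_measurement", 60.0, "mL/min")])])
        findings = derive_visit_findings(
            store.visits["v1"], store.events_of_visit("v1"), rules
        )
        assert [f.positive for f in findings] == [False]  # normal observation only

    def test_acr_in_mg_per_mmol_converted(self, rules):
        # 5.0 mg/mmol = 44.2 mg/g > 30 -> abnormal
        store = _store([(0, "cardiology",
                         [("measurement", "acr_measurement", 5.0, "mg/mmol")])])
        (finding,) = derive_visit_findings(
            store.visits["v1"], store.events_of_visit("v1"), rules
        )
        assert finding.concept_id == "elevated_acr" and finding.positive
        assert convert_value(5.0, "mg/mmol", "mg/g") == pytest.approx(44.2)

    def test_potassium_triple_collapses_to_one_hypernym(self, rules, hmap):
        """Diagnosis, test result and drug all abstract to abnormal blood potassium."""
        store = _store([(0, "cardiology", [
            ("diagnosis", "hyperkalemia_dx", None, None),
            ("measurement", "serum_potassium_measurement", 5.8, "mmol/L"),
            ("drug", "potassium_binder_rx", None, None),
        ])])
        findings = derive_visit_findings(
            store.visits["v1"], store.events_of_visit("v1"), rules
        )
        assert len(findings) == 3
        assert {hmap.hypernym_for(f.concept_id) for f in findings} == {
            "abnormal_blood_potassium"
        }
        intermediate = abstract_findings(findings, hmap, "0" * 64)
        assert len(intermediate) == 1
        assert intermediate[0].hypernym_concept_id == "abnormal_blood_potassium"

    def test_per_visit_locality(self, rules):
        """Findings of a visit do not depend on the other visits present."""
        full = _store([
            (0, "cardiology", [("measurement", "egfr_measurement", 55.0, "mL/min")]),
            (40, "urology", [("diagnosis", "diabetes_mellitus_dx", None, None)]),
        ])
        alone = _store([(0, "cardiology",
                         [("measurement", "egfr_measurement", 55.0, "mL/min")])])
        f_full = derive_visit_findings(full.visits["v1"],
                                       full.events_of_visit("v1"), rules)
        f_alone = derive_visit_findings(alone.visits["v1"],
                                        alone.events_of_visit("v1"), rules)
        assert [(f.concept_id, f.positive) for f in f_full] == [
            (f.concept_id, f.positive) for f in f_alone
        ]


class TestAbstractFindings:
    def test_kidney_leaf_becomes_abnormal_kidney_function(self, rules, hmap, vocab):
        store = _store([(0, "cardiology",
                         [("measurement", "egfr_measurement", 40.0, "mL/min")])])
        findings = derive_person_findings(store, "p1", rules)
        out = abstract_findings(findings, hmap, "0" * 64)
        assert [i.hypernym_concept_id for i in out] == ["abnormal_kidney_function"]

    def test_empty_input_empty_output(self, hmap):
        assert abstract_findings([], hmap, "0" * 64) == ()

    def test_no_leak_in_serialization(self, rules, hmap):
        """Serialized intermediate findings expose no identity, value or leaf."""
        store = _store([(0, "cardiology", [
            ("measurement", "egfr_measurement", 41.5, "mL/min"),
            ("measurement", "serum_potassium_measurement", 5.8, "mmol/L"),
        ])])
        findings = derive_person_findings(store, "p1", rules)
        digest = "a" * 64
        blob = repr(abstract_findings(findings, hmap, digest))
        assert IDENTITY not in blob
        assert "41.5" not in blob and "5.8" not in blob
        assert "decreased_egfr" not in blob and "high_serum_potassium" not in blob

    def test_rules_yaml_round_trip(self, rules, tmp_path):
        path = tmp_path / "rules.yaml"
        save_rules(rules, path)
        reloaded = load_rules(path)
        assert reloaded == rules


class TestDetectCkdCriteria:
    def test_sixteen_month_pair_met(self):
        """Two abnormal findings spanning Apr 2019 to Aug 2020 meet the rule."""
        obs = [
            IntermediateFinding("0" * 64, date("2019-04-04"),
                                "abnormal_kidney_function", True),
            IntermediateFinding("0" * 64, date("2020-08-02"),
                                "abnormal_kidney_function", True),
        ]
        verdict = detect_ckd_criteria(obs)
        assert verdict.met and verdict.first_met_date == date("2020-08-02")
        assert verdict.supporting_pair[0].date == date("2019-04-04")

    def test_recovery_resets_the_chain(self):
        verdict = detect_ckd_criteria(_obs([(0, True), (60, False), (150, True)]))
        assert not verdict.met

    def test_window_boundary_inclusive_at_90(self):
        assert not detect_ckd_criteria(_obs([(0, True), (89, True)])).met
        assert detect_ckd_criteria(_obs([(0, True), (90, True)])).met

    def test_same_day_normal_does_not_block_endpoint(self):
        # normal on the same day as the closing abnormal is not strictly between
        verdict = detect_ckd_criteria(_obs([(0, True), (100, False), (100, True)]))
        assert verdict.met

    @given(data=st.data())
    def test_matches_brute_force(self, data):
        n = data.draw(st.integers(0, 12), label="n")
        days = data.draw(
            st.lists(st.integers(0, 400), min_size=n, max_size=n), label="days"
        )
        labels = data.draw(
            st.lists(st.booleans(), min_size=n, max_size=n), label="labels"
        )
        pairs = list(zip(days, labels))
        verdict = detect_ckd_criteria(_obs(pairs))
        base = dt.date(2019, 1, 1)
        met, first = brute_force_chronicity(
            [(base + dt.timedelta(days=d), p) for d, p in pairs]
        )
        assert verdict.met == met
        assert verdict.first_met_date == first

    @given(data=st.data())
    def test_adding_abnormal_never_unmeets(self, data):
        n = data.draw(st.integers(1, 10))
        pairs = [
            (data.draw(st.integers(0, 300)), data.draw(st.booleans()))
            for _ in range(n)
        ]
        extra_day = data.draw(st.integers(0, 300))
        before = detect_ckd_criteria(_obs(pairs)).met
        after = detect_ckd_criteria(_obs(pairs + [(extra_day, True)])).met
        assert after or not before
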