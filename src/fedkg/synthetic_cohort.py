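"""Seeded multi-hospital synthetic cohort with planted kidney-disease phenotypes.

The real study data (three-hospital EHR extracts) are proprietary, so this
module is the test bed: it emits per-hospital stores whose patients are
fragmented across 2-3 hospitals under a shared citizen-identity string, with
longitudinal kidney-function series engineered per phenotype:

* ``multicenter_ckd`` — abnormal kidney results split across hospitals such
  that only the union satisfies the 90-day chronicity rule;
* ``transferred_ckd`` — one hospital's data alone satisfy the rule, after
  which the patient turns up at another hospital that holds no kidney tests;
* ``recovery_confounder`` — abnormal, then normal, then abnormal again, so
  the recovery reset must block the chronicity chain;
* ``control`` — normal kidney panel plus assorted comorbidity background.

Exclusion decoys (nephrology visits / kidney-disease diagnoses) exercise the
cohort-entry exclusion path.  Every emitted patient is re-verified against
the chronicity rule before the consortium is returned, and the whole
construction is a pure function of the configuration seed.

Control measurement distributions follow the study population's reported
means and spreads (blood potassium 4.27±0.46 mmol/L, blood glucose
5.97±1.92 mmol/L, and so on); abnormal values are drawn from ranges beyond
the rule thresholds.
"""

from __future__ import annotations

import datetime as dt
import json
from collections import namedtuple
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._util import parse_date, stable_seed
from .ehr_store import EHRStore, EventRecord, PersonRecord, VisitRecord
from .local_reasoning import detect_ckd_criteria

PHENOTYPES = ("multicenter_ckd", "transferred_ckd", "recovery_confounder", "control")
DECOY_PHENOTYPE = "excluded_decoy"

DEPARTMENTS = (
    "cardiovascular_medicine",
    "emergency",
    "gastroenterology",
    "ophthalmology",
    "orthopedics",
    "endocrinology",
    "urology",
    "respiratory_medicine",
    "cardiology",
    "infectious_disease",
)

COMORBIDITY_DX = (
    "diabetes_mellitus_dx",
    "essential_hypertension_dx",
    "coronary_heart_disease_dx",
    "mixed_hyperlipidemia_dx",
)

RISK_MEASUREMENTS = {
    # concept: (abnormal low, abnormal high, unit)
    "serum_potassium_measurement": (5.6, 6.3, "mmol/L"),
    "blood_glucose_measurement": (7.5, 11.0, "mmol/L"),
    "bun_measurement": (9.0, 15.0, "mmol/L"),
    "uric_acid_measurement": (430.0, 560.0, "µmol/L"),
}


class ConfigError(ValueError):
    """Infeasible or inconsistent cohort configuration."""


class GeneratorError(RuntimeError):
    """A planted patient failed its own phenotype oracle re-check."""


@dataclass
class CohortConfig:
    n_hospitals: int = 3
    n_patients: int = 100
    phenotype_fractions: dict = field(
        default_factory=lambda: {
            "multicenter_ckd": 0.15,
            "transferred_ckd": 0.15,
            "recovery_confounder": 0.10,
            "control": 0.60,
        }
    )
    decoy_fraction: float = 0.05
    study_start: dt.date = dt.date(2016, 1, 1)
    study_end: dt.date = dt.date(2020, 11, 30)
    seed: int = 42
    visit_rate: float = 3.0  # mean background visits per patient-year
    measurement_noise_sd: dict = field(
        default_factory=lambda: {
            "serum_potassium_measurement": 0.46,
            "blood_glucose_measurement": 1.0,
            "bun_measurement": 1.5,
            "uric_acid_measurement": 60.0,
            "serum_creatinine_measurement": 12.0,
            "egfr_measurement": 8.0,
        }
    )

    @property
    def window_days(self) -> int:
        return (self.study_end - self.study_start).days

    def validate(self) -> "CohortConfig":
        if self.n_hospitals < 2:
            raise ConfigError("need at least 2 hospitals")
        if self.n_patients < 0 or self.decoy_fraction < 0:
            raise ConfigError("negative sizes")
        total = sum(self.phenotype_fractions.get(p, 0.0) for p in PHENOTYPES)
        if abs(total - 1.0) > 1e-6:
            raise ConfigError(f"phenotype fractions sum to {total}, expected 1")
        if self.window_days < 365:
            raise ConfigError("study window must span at least 12 months")
        if self.window_days < 420:
            raise ConfigError(
                "study window too short to plant 90-day chronicity trajectories"
            )
        return self


@dataclass
class GroundTruth:
    identity: str
    phenotype: str
    excluded: bool = False
    onset_date: Optional[dt.date] = None
    per_hospital_satisfiable: dict = field(default_factory=dict)
    transfer_date: Optional[dt.date] = None
    diagnosis_date: Optional[dt.date] = None
    person_ids: dict = field(default_factory=dict)  # hospital_id -> person_id
    hospitals: tuple = ()

    def to_json(self) -> str:
        return json.dumps(
            {
                "identity": self.identity,
                "phenotype": self.phenotype,
                "excluded": self.excluded,
                "onset_date": self.onset_date.isoformat() if self.onset_date else None,
                "per_hospital_satisfiable": {
                    h: (d.isoformat() if d else None)
                    for h, d in sorted(self.per_hospital_satisfiable.items())
                },
                "transfer_date": self.transfer_date.isoformat()
                if self.transfer_date
                else None,
                "diagnosis_date": self.diagnosis_date.isoformat()
                if self.diagnosis_date
                else None,
                "person_ids": dict(sorted(self.person_ids.items())),
                "hospitals": list(self.hospitals),
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, line: str) -> "GroundTruth":
        d = json.loads(line)
        return cls(
            identity=d["identity"],
            phenotype=d["phenotype"],
            excluded=d["excluded"],
            onset_date=parse_date(d["onset_date"]) if d["onset_date"] else None,
            per_hospital_satisfiable={
                h: (parse_date(v) if v else None)
                for h, v in d["per_hospital_satisfiable"].items()
            },
            transfer_date=parse_date(d["transfer_date"]) if d["transfer_date"] else None,
            diagnosis_date=parse_date(d["diagnosis_date"])
            if d["diagnosis_date"]
            else None,
            person_ids=d["person_ids"],
            hospitals=tuple(d["hospitals"]),
        )


# ---------------------------------------------------------------------

_Obs = namedtuple("_Obs", ["date", "positive"])


class _StoreBuilder:
    def __init__(self, hospital_id: str):
        self.store = EHRStore(hospital_id=hospital_id)
        self._np = 0
        self._nv = 0
        self._ne = 0

    def add_person(self, identity: str, birth_year: int, sex: str) -> str:
        self._np += 1
        pid = f"p{self._np:06d}"
        self.store.persons[pid] = PersonRecord(
            person_id=pid, identity=identity, birth_year=birth_year, sex=sex
        )
        return pid

    def add_visit(self, person_id: str, date: dt.date, department: str) -> str:
        self._nv += 1
        vid = f"v{self._nv:06d}"
        self.store.visits[vid] = VisitRecord(
            visit_id=vid,
            person_id=person_id,
            hospital_id=self.store.hospital_id,
            visit_date=date,
            department=department,
        )
        return vid

    def add_event(self, visit_id, kind, concept_id, date, value=None, unit=None) -> str:
        self._ne += 1
        eid = f"e{self._ne:06d}"
        self.store.events[eid] = EventRecord(
            event_id=eid,
            visit_id=visit_id,
            kind=kind,
            concept_id=concept_id,
            value=value,
            unit=unit,
            event_date=date,
        )
        return eid


class _PatientPlan:
    """Relative-day plan for one patient, materialized after span is known."""

    def __init__(self):
        # (hospital, day) -> {"department": str|None, "events": [...]}
        self.slots: dict[tuple[str, int], dict] = {}

    def visit(self, hospital: str, day: int, department: Optional[str] = None) -> None:
        slot = self.slots.setdefault(
            (hospital, int(day)), {"department": None, "events": []}
        )
        if department is not None and slot["department"] is None:
            slot["department"] = department

    def event(self, hospital, day, kind, concept, value=None, unit=None) -> None:
        self.visit(hospital, day)
        self.slots[(hospital, int(day))]["events"].append((kind, concept, value, unit))

    @property
    def span(self) -> int:
        return max((d for _, d in self.slots), default=0)

    def hospitals(self) -> set[str]:
        return {h for h, _ in self.slots}


def _identity(rng: np.random.Generator, birth_year: int) -> str:
    """Synthetic 18-character citizen-ID-like token."""
    region = f"33{rng.integers(0, 10000):04d}"
    month = int(rng.integers(1, 13))
    day = int(rng.integers(1, 29))
    seq = f"{rng.integers(0, 1000):03d}"
    body = f"{region}{birth_year:04d}{month:02d}{day:02d}{seq}"
    checksum = sum(int(c) for c in body) % 11
    return body + ("X" if checksum == 10 else str(checksum))


def _round1(x: float) -> float:
    return round(float(x), 1)


def _abnormal_kidney_event(plan, rng, hospital, day) -> None:
    """Plant one abnormal kidney measurement (eGFR or ACR)."""
    if rng.random() < 0.7:
        plan.event(
            hospital, day, "measurement", "egfr_measurement",
            _round1(rng.uniform(30, 55)), "mL/min",
        )
    else:
        value = rng.uniform(45, 250)  # mg/g, comfortably above threshold
        if rng.random() < 0.25:  # exercise the mg/mmol conversion path
            plan.event(
                hospital, day, "measurement", "acr_measurement",
                _round1(value / 8.84), "mg/mmol",
            )
        else:
            plan.event(
                hospital, day, "measurement", "acr_measurement", _round1(value), "mg/g"
            )


def _plan_kidney_trajectory(phenotype, rng, hospitals) -> tuple[_PatientPlan, dict]:
    """Plant the phenotype-defining kidney event series (relative days)."""
    plan = _PatientPlan()
    meta: dict = {"onset_day": None, "transfer_day": None, "satisfiable": {}}
    a, b = hospitals[0], hospitals[1]
    if phenotype == "multicenter_ckd":
        _abnormal_kidney_event(plan, rng, a, 0)
        if rng.random() < 0.5:
            _abnormal_kidney_event(plan, rng, a, int(rng.integers(15, 61)))
        db = int(rng.integers(95, 191))
        _abnormal_kidney_event(plan, rng, b, db)
        if rng.random() < 0.4:
            _abnormal_kidney_event(plan, rng, b, db + int(rng.integers(10, 41)))
        meta["onset_day"] = db
    elif phenotype == "transferred_ckd":
        _abnormal_kidney_event(plan, rng, a, 0)
        da2 = int(rng.integers(95, 181))
        _abnormal_kidney_event(plan, rng, a, da2)
        meta["onset_day"] = da2
        meta["satisfiable"][a] = da2
        dt_day = da2 + int(rng.integers(30, 151))
        meta["transfer_day"] = dt_day
        plan.visit(b, dt_day, str(rng.choice(DEPARTMENTS)))
        if rng.random() < 0.5:
            plan.visit(b, dt_day + int(rng.integers(20, 61)), str(rng.choice(DEPARTMENTS)))
    elif phenotype == "recovery_confounder":
        _abnormal_kidney_event(plan, rng, a, 0)
        dn = int(rng.integers(30, 81))
        plan.event(
            a, dn, "measurement", "egfr_measurement",
            _round1(rng.uniform(65, 95)), "mL/min",
        )
        dr = dn + int(rng.integers(60, 141))
        _abnormal_kidney_event(plan, rng, a, dr)
        plan.visit(b, int(rng.integers(0, dr + 1)), str(rng.choice(DEPARTMENTS)))
    elif phenotype == "control":
        span = int(rng.integers(200, 601))
        for _ in range(int(rng.integers(1, 4))):
            h = hospitals[int(rng.integers(0, len(hospitals)))]
            plan.event(
                h, int(rng.integers(0, span + 1)), "measurement", "egfr_measurement",
                _round1(rng.uniform(65, 100)), "mL/min",
            )
    else:
        raise ConfigError(f"unknown phenotype {phenotype!r}")
    return plan, meta


def plant_ckd_trajectory(
    phenotype: str, rng: np.random.Generator, hospitals: tuple[str, ...]
) -> tuple[_PatientPlan, dict]:
    """Public wrapper: phenotype-defining visit/event series in relative days."""
    if phenotype in ("multicenter_ckd", "transferred_ckd") and len(hospitals) < 2:
        raise ConfigError(f"{phenotype} needs at least 2 hospitals")
    return _plan_kidney_trajectory(phenotype, rng, hospitals)


def _add_background(plan, rng, hospitals, phenotype, config) -> None:
    span = max(plan.span, 180)
    positive_like = phenotype != "control"
    n_bg = min(int(rng.poisson(config.visit_rate * span / 365.0)), 8)
    for _ in range(n_bg):
        h = hospitals[int(rng.integers(0, len(hospitals)))]
        day = int(rng.integers(0, span + 1))
        plan.visit(h, day, str(rng.choice(DEPARTMENTS)))
        if rng.random() < 0.35:
            plan.event(h, day, "diagnosis", str(rng.choice(COMORBIDITY_DX)))
        if rng.random() < 0.4:
            concept = str(rng.choice(sorted(RISK_MEASUREMENTS)))
            lo, hi, unit = RISK_MEASUREMENTS[concept]
            sd = config.measurement_noise_sd.get(concept, 1.0)
            if positive_like and rng.random() < 0.25:
                value = rng.uniform(lo, hi)  # an abnormal background risk
            else:
                centre = {"serum_potassium_measurement": 4.27,
                          "blood_glucose_measurement": 5.5,
                          "bun_measurement": 6.5,
                          "uric_acid_measurement": 330.0}[concept]
                value = float(np.clip(rng.normal(centre, sd), lo * 0.4, lo * 0.97))
            plan.event(h, day, "measurement", concept, _round1(value), unit)
        if not positive_like and rng.random() < 0.3:
            # controls also carry normal kidney-panel chemistry
            plan.event(
                h, day, "measurement", "serum_creatinine_measurement",
                _round1(np.clip(rng.normal(85, config.measurement_noise_sd.get(
                    "serum_creatinine_measurement", 12.0)), 50, 110)),
                "µmol/L",
            )
    # positives carry extra risk evidence inside the plant window
    if positive_like and phenotype != "control":
        last = plan.span
        for _ in range(int(rng.integers(1, 4))):
            h = hospitals[int(rng.integers(0, len(hospitals)))]
            day = int(rng.integers(0, last + 1))
            if rng.random() < 0.5:
                plan.event(h, day, "diagnosis", str(rng.choice(COMORBIDITY_DX)))
            else:
                concept = str(rng.choice(sorted(RISK_MEASUREMENTS)))
                lo, hi, unit = RISK_MEASUREMENTS[concept]
                plan.event(
                    h, day, "measurement", concept, _round1(rng.uniform(lo, hi)), unit
                )
    for h in hospitals:  # fragmentation: every assigned hospital sees the patient
        if h not in plan.hospitals():
            plan.visit(h, int(rng.integers(0, span + 1)), str(rng.choice(DEPARTMENTS)))


def _kidney_obs(plan) -> dict[str, list[_Obs]]:
    """Per-hospital kidney-finding series implied by planted raw values."""
    out: dict[str, list[_Obs]] = {}
    for (h, day), slot in plan.slots.items():
        for kind, concept, value, unit in slot["events"]:
            if kind != "measurement":
                continue
            if concept == "egfr_measurement":
                out.setdefault(h, []).append(_Obs(day, value < 60.0))
            elif concept == "acr_measurement":
                v = value * 8.84 if unit == "mg/mmol" else value
                out.setdefault(h, []).append(_Obs(day, v > 30.0))
            elif concept == "serum_creatinine_measurement" and value > 115.0:
                out.setdefault(h, []).append(_Obs(day, True))
    for obs in out.values():
        obs.sort(key=lambda o: o.date)
    return out


class _DayObs:
    __slots__ = ("date", "positive")

    def __init__(self, day: int, positive: bool):
        self.date = dt.date(2000, 1, 1) + dt.timedelta(days=day)
        self.positive = positive


def _verdict(obs: list[_Obs]):
    return detect_ckd_criteria([_DayObs(o.date, o.positive) for o in obs])


def _verify_plan(phenotype, plan, meta) -> None:
    """Oracle re-check of the planted per-hospital satisfiability pattern."""
    per_h = _kidney_obs(plan)
    union = sorted((o for obs in per_h.values() for o in obs), key=lambda o: o.date)
    uv = _verdict(union)
    epoch = dt.date(2000, 1, 1)
    if phenotype == "multicenter_ckd":
        if not uv.met or (uv.first_met_date - epoch).days != meta["onset_day"]:
            raise GeneratorError("multicenter union pattern violated")
        if any(_verdict(obs).met for obs in per_h.values()):
            raise GeneratorError("multicenter patient satisfiable at a single hospital")
    elif phenotype == "transferred_ckd":
        met_hosps = [h for h, obs in per_h.items() if _verdict(obs).met]
        if len(met_hosps) != 1 or not uv.met:
            raise GeneratorError("transferred pattern violated")
        if (uv.first_met_date - epoch).days != meta["onset_day"]:
            raise GeneratorError("transferred onset mismatch")
        if meta["transfer_day"] <= meta["onset_day"]:
            raise GeneratorError("transfer precedes satisfiability")
    elif phenotype == "recovery_confounder":
        if uv.met or any(_verdict(obs).met for obs in per_h.values()):
            raise GeneratorError("recovery confounder is satisfiable")
    elif phenotype == "control":
        if any(o.positive for o in union):
            raise GeneratorError("control has an abnormal kidney value")


def _materialize(
    plan, builders, hospitals, identity, birth_year, sex, rng, t_start, truth
) -> None:
    pids = {}
    for h in sorted(plan.hospitals()):
        pids[h] = builders[h].add_person(identity, birth_year, sex)
    for (h, day) in sorted(plan.slots):
        slot = plan.slots[(h, day)]
        date = t_start + dt.timedelta(days=day)
        department = slot["department"] or str(rng.choice(DEPARTMENTS))
        vid = builders[h].add_visit(pids[h], date, department)
        for kind, concept, value, unit in slot["events"]:
            builders[h].add_event(vid, kind, concept, date, value, unit)
    truth.person_ids = pids
    truth.hospitals = tuple(sorted(plan.hospitals()))


def _phenotype_counts(config: CohortConfig) -> dict[str, int]:
    counts = {
        p: int(round(config.phenotype_fractions.get(p, 0.0) * config.n_patients))
        for p in PHENOTYPES
    }
    counts["control"] += config.n_patients - sum(counts.values())
    if counts["control"] < 0:
        raise ConfigError("rounded phenotype counts exceed n_patients")
    return counts


def generate_consortium(
    config: CohortConfig,
) -> tuple[list[EHRStore], list[GroundTruth]]:
    """Generate the per-hospital stores and ground-truth labels.

    Deterministic given ``config.seed``; every emitted patient is re-checked
    against the chronicity oracle before the consortium is returned.
    """
    config.validate()
    hospitals = [f"H{i + 1}" for i in range(config.n_hospitals)]
    builders = {h: _StoreBuilder(h) for h in hospitals}
    truths: list[GroundTruth] = []

    labels: list[str] = []
    for p in PHENOTYPES:
        labels.extend([p] * _phenotype_counts(config)[p])

    for idx, phenotype in enumerate(labels):
        rng = np.random.default_rng(stable_seed(config.seed, "patient", idx))
        birth_year = int(rng.integers(1935, 1976))
        sex = "female" if rng.random() < 0.4 else "male"
        identity = _identity(rng, birth_year)
        n_h = int(min(config.n_hospitals, 2 if rng.random() < 0.7 else 3))
        pat_hosp = tuple(rng.choice(hospitals, size=n_h, replace=False))
        plan, meta = _plan_kidney_trajectory(phenotype, rng, pat_hosp)
        _add_background(plan, rng, pat_hosp, phenotype, config)
        _verify_plan(phenotype, plan, meta)

        max_t0 = config.window_days - plan.span - 1
        if max_t0 < 0:
            raise ConfigError("study window too short for a planted trajectory")
        t_start = config.study_start + dt.timedelta(days=int(rng.integers(0, max_t0 + 1)))

        truth = GroundTruth(identity=identity, phenotype=phenotype)
        if meta["onset_day"] is not None:
            truth.onset_date = t_start + dt.timedelta(days=meta["onset_day"])
            truth.diagnosis_date = truth.onset_date + dt.timedelta(
                days=int(rng.integers(90, 701))
            )
        if meta["transfer_day"] is not None:
            truth.transfer_date = t_start + dt.timedelta(days=meta["transfer_day"])
        truth.per_hospital_satisfiable = {
            h: (
                t_start + dt.timedelta(days=meta["satisfiable"][h])
                if h in meta["satisfiable"]
                else None
            )
            for h in pat_hosp
        }
        _materialize(plan, builders, hospitals, identity, birth_year, sex, rng,
                     t_start, truth)
        truths.append(truth)

    n_decoys = int(round(config.decoy_fraction * config.n_patients))
    exclusion_noise(builders, truths, config, n_decoys)

    stores = [builders[h].store.validate() for h in hospitals]
    return stores, truths


def exclusion_noise(builders, truths, config: CohortConfig, n_decoys: int) -> None:
    """Add decoy patients that the cohort-entry exclusion must rule out.

    Each decoy carries an otherwise-alarming abnormal kidney pair at one
    hospital plus either a nephrology visit or a kidney-disease diagnosis,
    so an unguarded pipeline would flag them.  Decoys are labelled
    ``excluded`` in ground truth.
    """
    hospitals = sorted(builders)
    for j in range(n_decoys):
        rng = np.random.default_rng(stable_seed(config.seed, "decoy", j))
        birth_year = int(rng.integers(1935, 1976))
        sex = "female" if rng.random() < 0.4 else "male"
        identity = _identity(rng, birth_year)
        pat_hosp = tuple(rng.choice(hospitals, size=2, replace=False))
        a, b = pat_hosp
        plan = _PatientPlan()
        _abnormal_kidney_event(plan, rng, a, 0)
        _abnormal_kidney_event(plan, rng, a, int(rng.integers(95, 181)))
        flag_hosp = a if rng.random() < 0.5 else b
        flag_day = int(rng.integers(0, plan.span + 1))
        if rng.random() < 0.5:
            plan.visit(flag_hosp, flag_day, "nephrology")
        else:
            plan.visit(flag_hosp, flag_day, str(rng.choice(DEPARTMENTS)))
            plan.event(flag_hosp, flag_day, "diagnosis", "ckd_dx")
        if b not in plan.hospitals():
            plan.visit(b, int(rng.integers(0, plan.span + 1)), str(rng.choice(DEPARTMENTS)))
        max_t0 = config.window_days - plan.span - 1
        t_start = config.study_start + dt.timedelta(days=int(rng.integers(0, max_t0 + 1)))
        truth = GroundTruth(identity=identity, phenotype=DECOY_PHENOTYPE, excluded=True)
        truth.per_hospital_satisfiable = {h: None for h in pat_hosp}
        _materialize(plan, builders, hospitals, identity, birth_year, sex, rng,
                     t_start, truth)
        truths.append(truth)


def write_ground_truth(truths: list[GroundTruth], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for t in truths:
            fh.write(t.to_json() + "\n")


def read_ground_truth(path) -> list[GroundTruth]:
    with open(path, "r", encoding="utf-8") as fh:
        return [GroundTruth.from_json(line) for line in fh if line.strip()]
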