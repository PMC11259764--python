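"""Shipped kidney-disease application content: vocabulary and rule set.

The disease-specific vocabulary covers the abnormal-kidney-function
criterion findings (decreased eGFR, elevated urine albumin-to-creatinine
ratio, elevated serum creatinine, eGFR stage G3b) and a ten-item risk
catalog (acute kidney injury history, elevated blood urea nitrogen,
elevated uric acid, urinary protein, diabetes, hypertension, cardiovascular
disease, hyperlipidemia, abnormal blood potassium, abnormal blood glucose).
Hypernym flags mark the concepts cleared for export; leaf embeddings are
synthetic vectors constructed so that leaves sharing a hypernym are
cohesive, standing in for learned embeddings which are data, not part of
the method.

Thresholds follow the screening criteria: eGFR strictly below 60 mL/min and
ACR strictly above 30 mg/g are abnormal; the remaining thresholds are
ordinary laboratory reference limits.
"""

from __future__ import annotations

import numpy as np

from ._util import stable_seed
from .local_reasoning import MappingRule, MeasurementRule, RuleSet
from .vocabulary import Concept, ConceptGraph, HypernymMap, build_hypernym_map

EMBED_DIM = 8

KIDNEY_HYPERNYM = "abnormal_kidney_function"

RISK_HYPERNYMS = (
    "aki_history",
    "elevated_bun",
    "elevated_uric_acid",
    "urinary_protein",
    "diabetes",
    "hypertension",
    "cardiovascular_disease",
    "hyperlipidemia",
    "abnormal_blood_potassium",
    "abnormal_blood_glucose",
)

# hypernym -> (domain, leaves)
_HYPERNYM_LEAVES = {
    KIDNEY_HYPERNYM: (
        "observation",
        ("decreased_egfr", "elevated_acr", "elevated_serum_creatinine", "egfr_g3b_stage"),
    ),
    "abnormal_blood_potassium": (
        "observation",
        ("hyperkalemia_dx", "high_serum_potassium", "potassium_binder_rx"),
    ),
    "abnormal_blood_glucose": ("observation", ("high_blood_glucose",)),
    "diabetes": ("condition", ("diabetes_mellitus_dx",)),
    "hypertension": ("condition", ("essential_hypertension_dx",)),
    "cardiovascular_disease": ("condition", ("coronary_heart_disease_dx",)),
    "hyperlipidemia": ("condition", ("mixed_hyperlipidemia_dx",)),
    "elevated_bun": ("observation", ("high_bun",)),
    "elevated_uric_acid": ("observation", ("high_uric_acid",)),
    "urinary_protein": ("observation", ("proteinuria_dx",)),
    "aki_history": ("condition", ("aki_dx",)),
}

_LEAF_DOMAIN_OVERRIDES = {
    "hyperkalemia_dx": "condition",
    "potassium_binder_rx": "drug",
    "diabetes_mellitus_dx": "condition",
    "essential_hypertension_dx": "condition",
    "coronary_heart_disease_dx": "condition",
    "mixed_hyperlipidemia_dx": "condition",
    "proteinuria_dx": "condition",
    "aki_dx": "condition",
}

KIDNEY_DIAGNOSES = ("ckd_dx", "glomerulonephritis_dx")

MEASUREMENT_CONCEPTS = {
    "egfr_measurement": "estimated glomerular filtration rate",
    "acr_measurement": "urine albumin-to-creatinine ratio",
    "serum_creatinine_measurement": "serum creatinine",
    "serum_potassium_measurement": "blood potassium",
    "blood_glucose_measurement": "blood glucose",
    "bun_measurement": "blood urea nitrogen",
    "uric_acid_measurement": "uric acid",
}

KIDNEY_MEASUREMENTS = (
    "egfr_measurement",
    "acr_measurement",
    "serum_creatinine_measurement",
)


def _embedding(rng_key: str, base: np.ndarray | None = None) -> tuple[float, ...]:
    rng = np.random.default_rng(stable_seed("embedding", rng_key))
    if base is None:
        vec = rng.standard_normal(EMBED_DIM)
    else:
        vec = base + 0.15 * rng.standard_normal(EMBED_DIM)
    vec = vec / np.linalg.norm(vec)
    return tuple(round(float(x), 6) for x in vec)


def ckd_concepts() -> list[Concept]:
    concepts: list[Concept] = [
        Concept("clinical_finding", "clinical finding", "observation"),
        Concept(
            "kidney_function_status",
            "kidney function status",
            "observation",
            parent_ids=frozenset({"clinical_finding"}),
        ),
        Concept(
            "ckd_risk",
            "kidney-disease related risk",
            "observation",
            parent_ids=frozenset({"clinical_finding"}),
        ),
        Concept(
            "kidney_disease",
            "kidney disease",
            "condition",
            parent_ids=frozenset({"clinical_finding"}),
        ),
        Concept("laboratory_test", "laboratory test", "measurement"),
    ]
    parent_of_hypernym = {
        KIDNEY_HYPERNYM: "kidney_function_status",
        **{h: "ckd_risk" for h in RISK_HYPERNYMS},
    }
    for hyp, (domain, leaves) in _HYPERNYM_LEAVES.items():
        base = np.asarray(
            _embedding(f"base:{hyp}"), dtype=float
        )  # cluster centre for this hypernym's leaves
        concepts.append(
            Concept(
                hyp,
                hyp.replace("_", " "),
                domain,
                parent_ids=frozenset({parent_of_hypernym[hyp]}),
                is_hypernym=True,
            )
        )
        for leaf in leaves:
            concepts.append(
                Concept(
                    leaf,
                    leaf.replace("_", " "),
                    _LEAF_DOMAIN_OVERRIDES.get(leaf, domain),
                    parent_ids=frozenset({hyp}),
                    embedding=_embedding(f"leaf:{leaf}", base),
                )
            )
    for dx in KIDNEY_DIAGNOSES:
        concepts.append(
            Concept(
                dx,
                dx.replace("_", " "),
                "condition",
                parent_ids=frozenset({"kidney_disease"}),
            )
        )
    concepts.append(
        Concept(
            "dialysis_procedure",
            "dialysis procedure",
            "procedure",
            parent_ids=frozenset({"kidney_disease"}),
        )
    )
    for cid, name in MEASUREMENT_CONCEPTS.items():
        concepts.append(
            Concept(
                cid, name, "measurement", parent_ids=frozenset({"laboratory_test"})
            )
        )
    return concepts


def ckd_vocabulary() -> ConceptGraph:
    return ConceptGraph(ckd_concepts())


def ckd_hypernym_map(
    graph: ConceptGraph | None = None, threshold: float = 0.7
) -> HypernymMap:
    return build_hypernym_map(graph or ckd_vocabulary(), threshold=threshold)


def ckd_ruleset() -> RuleSet:
    measurement_rules = (
        MeasurementRule(
            "R_EGFR_LT_60", "egfr_measurement", "<", 60.0, "mL/min",
            "decreased_egfr", emit_negative=True,
        ),
        MeasurementRule(
            "R_ACR_GT_30", "acr_measurement", ">", 30.0, "mg/g",
            "elevated_acr", emit_negative=True,
        ),
        MeasurementRule(
            "R_SCR_GT_115", "serum_creatinine_measurement", ">", 115.0, "µmol/L",
            "elevated_serum_creatinine",
        ),
        MeasurementRule(
            "R_K_GT_5_5", "serum_potassium_measurement", ">", 5.5, "mmol/L",
            "high_serum_potassium",
        ),
        MeasurementRule(
            "R_GLU_GT_7", "blood_glucose_measurement", ">", 7.0, "mmol/L",
            "high_blood_glucose",
        ),
        MeasurementRule(
            "R_BUN_GT_8", "bun_measurement", ">", 8.0, "mmol/L", "high_bun",
        ),
        MeasurementRule(
            "R_UA_GT_420", "uric_acid_measurement", ">", 420.0, "µmol/L",
            "high_uric_acid",
        ),
    )
    diagnosis_leaves = (
        "hyperkalemia_dx",
        "diabetes_mellitus_dx",
        "essential_hypertension_dx",
        "coronary_heart_disease_dx",
        "mixed_hyperlipidemia_dx",
        "proteinuria_dx",
        "aki_dx",
    )
    mapping_rules = tuple(
        MappingRule(f"R_DX_{c.upper()}", "diagnosis", c, c) for c in diagnosis_leaves
    ) + (MappingRule("R_RX_POTASSIUM_BINDER", "drug", "potassium_binder_rx", "potassium_binder_rx"),)
    return RuleSet(
        measurement_rules=measurement_rules,
        mapping_rules=mapping_rules,
        window_days=90,
        kidney_hypernym=KIDNEY_HYPERNYM,
        abnormal_kidney_findings=frozenset(
            {"decreased_egfr", "elevated_acr", "elevated_serum_creatinine", "egfr_g3b_stage"}
        ),
        kidney_measurements=frozenset(KIDNEY_MEASUREMENTS),
        kidney_diagnoses=frozenset(KIDNEY_DIAGNOSES),
        nephrology_departments=frozenset({"nephrology"}),
        risk_hypernyms=frozenset(RISK_HYPERNYMS),
    )
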