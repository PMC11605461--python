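"""Construction of the synthetic 450-group curated vocabulary.

The clinical mapping from ~30k raw terminology codes down to ~450 curated
groups is input data in real use. For synthetic cohorts (and the bundled demo
map) this module lays out a 450-group vocabulary with the same *shape*: named
diagnostic groups (lung cancer, other cancers, chronic respiratory, other
chronic conditions), a core of named symptoms / tests / procedures /
medications / encounter sites, generic filler groups up to the target size,
and a handful of administrative groups that curation must drop. Each curated
group is reachable from 3 synthetic raw codes so the many-to-one curation
stage is genuinely exercised.
"""

from __future__ import annotations

from pathdx.curation import CodeMap, build_code_map

LUNG_DX = "lung_cancer_dx"

OTHER_CANCER_DX = (
    "breast_cancer_dx",
    "colorectal_cancer_dx",
    "prostate_cancer_dx",
    "gastric_cancer_dx",
    "renal_cancer_dx",
    "blood_cancer_dx",
    "skin_cancer_dx",
    "pancreatic_cancer_dx",
)

RESPIRATORY_DX = (
    "copd_dx",
    "asthma_dx",
    "bronchiectasis_dx",
    "pulmonary_fibrosis_dx",
    "resp_infection_dx",
)

OTHER_DX = (
    "diabetes_dx",
    "hypertension_dx",
    "ihd_dx",
    "ckd_dx",
    "atrial_fib_dx",
    "depression_dx",
    "osteoarthritis_dx",
    "hypothyroid_dx",
    "obesity_dx",
    "anaemia_dx",
)

NAMED_SYMPTOMS = (
    "cough",
    "dyspnoea",
    "haemoptysis",
    "chest_pain",
    "weight_loss",
    "fatigue",
    "wheeze",
    "chest_infection",
    "hoarseness",
    "back_pain",
    "shoulder_pain",
    "loss_of_appetite",
    "night_sweats",
    "dizziness",
    "palpitations",
    "abdominal_pain",
    "headache",
    "insomnia",
    "joint_pain",
    "rash",
)

NAMED_TESTS = (
    "chest_xray",
    "spirometry",
    "full_blood_count",
    "crp_test",
    "liver_function_test",
    "renal_function_test",
    "hba1c_test",
    "ecg",
    "oxygen_saturation",
    "peak_flow",
)

NAMED_PROCEDURES = (
    "copd_monitoring",
    "asthma_review",
    "diabetes_review",
    "medication_review",
    "smoking_cessation_advice",
    "flu_vaccination",
    "referral_chest_clinic",
    "referral_2ww",
    "blood_pressure_check",
    "wound_dressing",
)

NAMED_MEDICATIONS = (
    "antibiotic_rx",
    "salbutamol_rx",
    "steroid_inhaler_rx",
    "oral_steroid_rx",
    "opioid_analgesic_rx",
    "simple_analgesic_rx",
    "statin_rx",
    "antihypertensive_rx",
    "metformin_rx",
    "ppi_rx",
)

NAMED_ENCOUNTERS = (
    "gp_surgery_visit",
    "gp_telephone_contact",
    "home_visit",
    "ae_attendance",
    "outpatient_attendance",
    "nurse_clinic_visit",
)

ADMIN_GROUPS = (
    "admin_registration",
    "admin_address_change",
    "admin_letter_received",
    "admin_record_merge",
    "admin_did_not_attend",
    "admin_data_entry",
)

#: raw codes per curated group in the synthetic mapping
RAW_CODES_PER_GROUP = 3


def named_groups() -> list[tuple[str, str]]:
    """(group_id, category) for all named clinical groups."""
    out: list[tuple[str, str]] = [(LUNG_DX, "diagnosis")]
    out += [(g, "diagnosis") for g in OTHER_CANCER_DX]
    out += [(g, "diagnosis") for g in RESPIRATORY_DX]
    out += [(g, "diagnosis") for g in OTHER_DX]
    out += [(g, "symptom") for g in NAMED_SYMPTOMS]
    out += [(g, "test") for g in NAMED_TESTS]
    out += [(g, "procedure") for g in NAMED_PROCEDURES]
    out += [(g, "medication") for g in NAMED_MEDICATIONS]
    out += [(g, "encounter_site") for g in NAMED_ENCOUNTERS]
    return out


_FILLER_CATEGORIES = ("symptom", "test", "procedure", "medication", "diagnosis")
_FILLER_PREFIX = {
    "symptom": "sym",
    "test": "tst",
    "procedure": "prc",
    "medication": "med",
    "diagnosis": "dxg",
}


def group_table(vocab_size: int = 450) -> list[tuple[str, str]]:
    """(group_id, category) for a vocabulary of ``vocab_size`` curated groups.

    Named groups come first; generic filler groups pad out to the target size.
    """
    named = named_groups()
    if vocab_size < len(named):
        raise ValueError(
            f"vocab_size={vocab_size} smaller than the {len(named)} named groups"
        )
    groups = list(named)
    i = 0
    while len(groups) < vocab_size:
        cat = _FILLER_CATEGORIES[i % len(_FILLER_CATEGORIES)]
        groups.append((f"{_FILLER_PREFIX[cat]}_{i:03d}", cat))
        i += 1
    return groups


def raw_codes_for(group_id: str) -> list[str]:
    return [f"{group_id}.{k}" for k in range(RAW_CODES_PER_GROUP)]


def make_code_map(vocab_size: int = 450) -> CodeMap:
    """Synthetic many-to-one code map: ``vocab_size`` curated groups, 3 raw
    codes each, plus administrative groups flagged for removal."""
    rows: list[tuple[str, str, str, str, bool]] = []
    for gid, cat in group_table(vocab_size):
        label = gid.replace("_", " ")
        for raw in raw_codes_for(gid):
            rows.append((raw, gid, label, cat, False))
    for gid in ADMIN_GROUPS:
        for raw in raw_codes_for(gid):
            rows.append((raw, gid, gid.replace("_", " "), "procedure", True))
    return build_code_map(rows)
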