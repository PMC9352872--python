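"""Baseline (pre-index) patient characteristics.

All measures use only claims dated in the 6-month window before the index
date, [index - 183 days, index - 1 day]: a modified Charlson comorbidity
index with CML excluded from the malignancy component, a configurable
mild/moderate/severe disease-complexity class, individual comorbidity
flags, hydroxyurea pretreatment use, and a "likely unfit for HSCT" flag
(age >= 75, congestive heart failure, cirrhosis, or end-stage renal
disease).  Age is index-date year minus birth year, the granularity claims
data carry.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import CCICondition, StudyConfig, any_code_matches, code_matches
from .cohort import PatientSelection
from .model import ClaimsBundle, split_codes


@dataclass
class BaselineProfile:
    patient_id: str
    age_at_index: int
    age_65_plus: bool
    sex: str
    region: str
    cci_score: int
    cci_category: str  # "0", "1", "2", "3+"
    darkow_class: str  # mild | moderate | severe
    hydroxyurea_pretreatment: bool
    hsct_unfit: bool
    comorbidities: dict[str, bool] = field(default_factory=dict)


def modified_cci(dx_codes: list[str], cci_map: dict[str, CCICondition]) -> int:
    """Charlson score over distinct conditions, with hierarchy rules.

    A condition scores when any baseline code matches one of its prefixes;
    a condition listed in another present condition's ``supersedes`` is
    dropped before summing (e.g. complicated diabetes supersedes
    uncomplicated).  The default map carries no CML codes, so CML never
    contributes.
    """
    present = {
        name
        for name, cond in cci_map.items()
        if any_code_matches(dx_codes, cond.codes)
    }
    superseded: set[str] = set()
    for name in present:
        superseded.update(s for s in cci_map[name].supersedes if s in present)
    return sum(cci_map[name].weight for name in present - superseded)


def cci_category(score: int) -> str:
    return str(score) if score < 3 else "3+"


def darkow_severity(codes: list[str], severity_map: dict[str, list[str]]) -> str:
    """Highest severity tier with a qualifying code; mild when none."""
    if any_code_matches(codes, severity_map.get("severe", [])):
        return "severe"
    if any_code_matches(codes, severity_map.get("moderate", [])):
        return "moderate"
    return "mild"


def hsct_unfit(age_at_index: int, flags: dict[str, bool], config: StudyConfig) -> bool:
    if age_at_index >= config.hsct_unfit_age:
        return True
    return any(flags.get(cond, False) for cond in config.hsct_unfit_conditions)


def baseline_profile(
    bundle: ClaimsBundle,
    sel: PatientSelection,
    config: StudyConfig,
) -> BaselineProfile:
    """Compute one cohort member's baseline profile."""
    pid = sel.patient_id
    start, end = sel.baseline_start, sel.baseline_end
    assert sel.index_date is not None and start is not None and end is not None

    med = bundle.medical
    med = med[med["patient_id"] == pid]
    ph = bundle.pharmacy
    ph = ph[ph["patient_id"] == pid]
    prow = bundle.patients[bundle.patients["patient_id"] == pid].iloc[0]

    dx_codes: list[str] = []
    proc_codes: list[str] = []
    for row in med.itertuples():
        if start <= row.start_date <= end:
            dx_codes.extend(split_codes(row.diagnosis_codes))
            proc_codes.extend(split_codes(row.procedure_codes))

    flags = {
        name: any_code_matches(dx_codes, prefixes)
        for name, prefixes in config.comorbidity_map.items()
    }
    hydroxyurea = any(
        row.drug == "hydroxyurea" and start <= row.fill_date <= end
        for row in ph.itertuples()
    )
    age = sel.index_date.year - int(prow["birth_year"])
    score = modified_cci(dx_codes, config.cci_map)
    return BaselineProfile(
        patient_id=pid,
        age_at_index=age,
        age_65_plus=age >= 65,
        sex=str(prow["sex"]),
        region=str(prow["region"]),
        cci_score=score,
        cci_category=cci_category(score),
        darkow_class=darkow_severity(dx_codes + proc_codes, config.darkow_map),
        hydroxyurea_pretreatment=hydroxyurea,
        hsct_unfit=hsct_unfit(age, flags, config),
        comorbidities=flags,
    )


def baseline_table(
    bundle: ClaimsBundle,
    selections: dict[str, PatientSelection],
    cohort_ids: list[str],
    config: StudyConfig,
) -> pd.DataFrame:
    """Table-1-style cohort summary of the baseline profiles."""
    profiles = [
        baseline_profile(bundle, selections[pid], config) for pid in sorted(cohort_ids)
    ]
    n = len(profiles)
    rows: list[dict] = []

    def add(measure: str, value, count=None):
        rows.append({"measure": measure, "value": value, "count": count, "n": n})

    if n == 0:
        return pd.DataFrame(rows, columns=["measure", "value", "count", "n"])

    ages = np.array([p.age_at_index for p in profiles], dtype=float)
    add("age_mean", float(ages.mean()))
    add("age_sd", float(ages.std(ddof=1)) if n > 1 else 0.0)
    add("age_median", float(np.median(ages)))
    add("age_65_plus", None, sum(p.age_65_plus for p in profiles))
    add("female", None, sum(p.sex == "F" for p in profiles))
    scores = np.array([p.cci_score for p in profiles], dtype=float)
    add("cci_mean", float(scores.mean()))
    add("cci_sd", float(scores.std(ddof=1)) if n > 1 else 0.0)
    add("cci_median", float(np.median(scores)))
    for cat in ("0", "1", "2", "3+"):
        add(f"cci_category_{cat}", None, sum(p.cci_category == cat for p in profiles))
    for cls in ("mild", "moderate", "severe"):
        add(f"darkow_{cls}", None, sum(p.darkow_class == cls for p in profiles))
    add("hydroxyurea_pretreatment", None, sum(p.hydroxyurea_pretreatment for p in profiles))
    add("hsct_unfit", None, sum(p.hsct_unfit for p in profiles))
    for cond in sorted(config.comorbidity_map):
        add(f"comorbidity_{cond}", None, sum(p.comorbidities[cond] for p in profiles))
    return pd.DataFrame(rows, columns=["measure", "value", "count", "n"])
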