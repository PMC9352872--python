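"""Study configuration: thresholds, windows, code lists, approval dates.

Every tunable of the analysis lives in :class:`StudyConfig` so that a run is
fully described by one object: the washout and gap thresholds that define
lines of therapy, the diagnosis/procedure code lists used for cohort
selection and cost attribution, FDA approval dates that gate which fills can
define a line, the medical-care CPI table used to express costs in
target-year dollars, and formatting/suppression rules for reporting.

Code matching throughout the package is by *prefix* (an ICD "205.1" entry
matches "205.11", "205.12", ...), case-insensitive, which mirrors the usual
"205.1x" notation of claims studies.
"""

from __future__ import annotations

import datetime as dt
from typing import Optional

import yaml
from pydantic import BaseModel, Field, model_validator

# Canonical drug tokens.  The six CML-CP line-defining drugs, plus
# hydroxyurea (pretreatment only, never line-defining) and "other".
CML_CP_DRUGS: tuple[str, ...] = (
    "bosutinib",
    "dasatinib",
    "imatinib",
    "nilotinib",
    "omacetaxine",
    "ponatinib",
)
TKI_DRUGS: tuple[str, ...] = (
    "bosutinib",
    "dasatinib",
    "imatinib",
    "nilotinib",
    "ponatinib",
)
ALL_DRUGS: tuple[str, ...] = CML_CP_DRUGS + ("hydroxyurea", "other")

FIRST_LINE_ELIGIBLE_DRUGS: tuple[str, ...] = (
    "bosutinib",
    "dasatinib",
    "imatinib",
    "nilotinib",
)


class ConfigError(ValueError):
    """Raised when the study configuration is inconsistent or incomplete."""


class ApprovalDates(BaseModel):
    """FDA approval dates for one drug.

    ``resistant_intolerant`` is the earliest (resistance/intolerance)
    indication; ``newly_diagnosed`` the later first-line expansion where one
    exists.  Fills before the earliest applicable date never define a line.
    """

    resistant_intolerant: dt.date
    newly_diagnosed: Optional[dt.date] = None

    @property
    def earliest(self) -> dt.date:
        return self.resistant_intolerant


class CodeLists(BaseModel):
    """Diagnosis / procedure code prefixes used by the analysis."""

    cml_dx: list[str] = ["205.1", "C92.1"]
    cml_dx_medicare: list[str] = ["9863", "9875", "35022"]
    cml_remission: list[str] = ["205.11", "C92.11"]
    cml_relapse: list[str] = ["205.12", "C92.12"]
    clinical_trial: list[str] = ["V70.7", "Z00.6"]
    hsct_procedures: list[str] = ["41.0", "38240", "38241", "30243"]
    ap_bc_chemo: list[str] = ["96413", "96415", "J9000", "J9100"]
    omacetaxine_procedures: list[str] = ["J9262"]


class CCICondition(BaseModel):
    """One Charlson condition: weight, code prefixes, hierarchy edges.

    ``supersedes`` lists milder conditions that must not also score when
    this one is present (e.g. complicated diabetes supersedes diabetes).
    """

    weight: int
    codes: list[str]
    supersedes: list[str] = []


def _default_cci_map() -> dict[str, CCICondition]:
    # Original 17-condition Charlson weights with the malignancy category
    # edited so that chronic myeloid leukemia codes (205.1x / C92.1x) never
    # contribute; the scored malignancy prefixes exclude them explicitly.
    c = CCICondition
    return {
        "myocardial_infarction": c(weight=1, codes=["410", "412", "I21", "I22", "I25.2"]),
        "congestive_heart_failure": c(weight=1, codes=["428", "I50"]),
        "peripheral_vascular": c(weight=1, codes=["441", "443.9", "I70", "I71"]),
        "cerebrovascular": c(
            weight=1,
            codes=["430", "431", "432", "433", "434", "435", "436", "437", "438",
                   "G45", "I60", "I61", "I62", "I63", "I64", "I65", "I66", "I67", "I69"],
        ),
        "dementia": c(weight=1, codes=["290", "F00", "F01", "F02", "F03", "G30"]),
        "chronic_pulmonary": c(
            weight=1,
            codes=["490", "491", "492", "493", "494", "495", "496",
                   "J40", "J41", "J42", "J43", "J44", "J45", "J46", "J47"],
        ),
        "rheumatic": c(weight=1, codes=["710.0", "710.1", "710.4", "714", "M05", "M06", "M32", "M33", "M34"]),
        "peptic_ulcer": c(weight=1, codes=["531", "532", "533", "534", "K25", "K26", "K27", "K28"]),
        "mild_liver": c(weight=1, codes=["571.2", "571.5", "571.6", "K70.3", "K74"]),
        "diabetes": c(weight=1, codes=["250.0", "250.1", "250.2", "250.3", "E10.9", "E11.9"]),
        "diabetes_complicated": c(
            weight=2,
            codes=["250.4", "250.5", "250.6", "250.7", "E10.2", "E11.2", "E11.3", "E11.4", "E11.5"],
            supersedes=["diabetes"],
        ),
        "hemiplegia": c(weight=2, codes=["342", "343", "G81", "G82"]),
        "renal": c(weight=2, codes=["582", "583", "585", "586", "N18", "N19"]),
        "malignancy": c(
            weight=2,
            codes=["140", "150", "160", "170", "180", "190", "200", "201", "202", "203",
                   "204", "205.0", "205.2", "205.3", "205.8", "205.9", "206", "207", "208",
                   "C00", "C18", "C34", "C50", "C61", "C81", "C82", "C83", "C85", "C90",
                   "C91", "C92.0", "C92.2", "C92.4", "C92.5", "C93", "C94", "C95"],
        ),
        "severe_liver": c(
            weight=3,
            codes=["572.2", "572.3", "572.4", "K72.9", "K76.6", "K76.7"],
            supersedes=["mild_liver"],
        ),
        "metastatic": c(
            weight=6,
            codes=["196", "197", "198", "199", "C77", "C78", "C79", "C80"],
            supersedes=["malignancy"],
        ),
        "aids": c(weight=6, codes=["042", "B20", "B21", "B22", "B24"]),
    }


def _default_comorbidity_map() -> dict[str, list[str]]:
    return {
        "cardiac_arrhythmias": ["427", "I47", "I48", "I49"],
        "chronic_pulmonary_disease": ["490", "491", "492", "493", "494", "495", "496",
                                      "J40", "J41", "J42", "J43", "J44", "J45", "J46", "J47"],
        "congestive_heart_failure": ["428", "I50"],
        "diabetes": ["250", "E10", "E11"],
        "hypertension": ["401", "402", "403", "404", "405",
                         "I10", "I11", "I12", "I13", "I15"],
        "valvular_disease": ["394", "395", "396", "397", "424",
                             "I05", "I06", "I07", "I08", "I34", "I35", "I36", "I37"],
        "cirrhosis": ["571.2", "571.5", "571.6", "K70.3", "K74.3", "K74.4", "K74.5", "K74.6"],
        "end_stage_renal_disease": ["585.6", "N18.6", "V45.11", "Z99.2"],
    }


def _default_darkow_map() -> dict[str, list[str]]:
    # Configurable stand-in tiers for the CML disease-complexity classifier:
    # the published code lists are not replicated; users supply their own.
    return {
        "moderate": ["285.9", "D64.9", "287.5", "D69.6", "780.79", "R53"],
        "severe": ["205.0", "C92.0", "038", "A41", "786.3", "R04.2"],
    }


def _default_cpi_table() -> dict[int, float]:
    # Annual medical-care component of the US consumer price index
    # (index levels; only ratios matter).  Replace with the exact series
    # for production use.
    return {
        2001: 272.8, 2002: 285.6, 2003: 297.1, 2004: 310.1, 2005: 323.2,
        2006: 336.2, 2007: 351.1, 2008: 364.1, 2009: 375.6, 2010: 388.4,
        2011: 400.3, 2012: 414.9, 2013: 425.1, 2014: 435.3, 2015: 446.8,
        2016: 463.7, 2017: 475.3, 2018: 484.7, 2019: 498.4,
    }


def _default_approval_dates() -> dict[str, ApprovalDates]:
    d = dt.date
    return {
        "imatinib": ApprovalDates(resistant_intolerant=d(2001, 5, 10)),
        "dasatinib": ApprovalDates(
            resistant_intolerant=d(2006, 6, 28), newly_diagnosed=d(2010, 10, 28)
        ),
        "nilotinib": ApprovalDates(
            resistant_intolerant=d(2007, 10, 29), newly_diagnosed=d(2010, 6, 17)
        ),
        "bosutinib": ApprovalDates(
            resistant_intolerant=d(2012, 9, 4), newly_diagnosed=d(2017, 12, 19)
        ),
        "ponatinib": ApprovalDates(resistant_intolerant=d(2012, 12, 14)),
        "omacetaxine": ApprovalDates(resistant_intolerant=d(2012, 10, 26)),
    }


def _default_drug_map() -> dict[str, str]:
    m = {name: name for name in ALL_DRUGS}
    m.update(
        {
            "gleevec": "imatinib",
            "sprycel": "dasatinib",
            "tasigna": "nilotinib",
            "bosulif": "bosutinib",
            "iclusig": "ponatinib",
            "synribo": "omacetaxine",
            "hydrea": "hydroxyurea",
        }
    )
    return m


def _default_generation_map() -> dict[str, str]:
    return {
        "imatinib": "1G",
        "dasatinib": "2G",
        "nilotinib": "2G",
        "bosutinib": "2G",
        "ponatinib": "3G",
        "omacetaxine": "other",
    }


class StudyConfig(BaseModel):
    """All thresholds, windows, code lists and formatting rules of the study.

    Day-count conventions: "6 months" = 183 days, "1 month" = 30 days,
    "3 months" = 91 days, "1 year" = 365 days for eligibility windows;
    PPPM month length = 365.25 / 12 = 30.4375 days; person-year =
    365.25 days.
    """

    washout_days: int = 183
    gap_days: int = 90
    dx_to_1l_before_days: int = 30
    dx_to_1l_after_days_commercial: int = 91
    dx_to_1l_after_days_medicare: int = 365
    post_dx_enrollment_days: int = 365
    baseline_days: int = 183
    enrollment_merge_gap_days: int = 0
    month_length_days: float = 365.25 / 12
    year_length_days: float = 365.25
    target_cost_year: int = 2019
    suppression_threshold: int = 11
    data_start: dt.date = dt.date(2001, 1, 1)
    data_end: dt.date = dt.date(2019, 6, 30)
    # "prorate": inpatient paid amounts split by fraction of stay days
    # inside the analysis window; "start": attributed wholly to the window
    # containing the admission date.
    ip_cost_attribution: str = "prorate"

    approval_dates: dict[str, ApprovalDates] = Field(default_factory=_default_approval_dates)
    codes: CodeLists = Field(default_factory=CodeLists)
    drug_map: dict[str, str] = Field(default_factory=_default_drug_map)
    generation_map: dict[str, str] = Field(default_factory=_default_generation_map)
    cpi_table: dict[int, float] = Field(default_factory=_default_cpi_table)
    cci_map: dict[str, CCICondition] = Field(default_factory=_default_cci_map)
    darkow_map: dict[str, list[str]] = Field(default_factory=_default_darkow_map)
    comorbidity_map: dict[str, list[str]] = Field(default_factory=_default_comorbidity_map)
    hsct_unfit_conditions: list[str] = Field(
        default_factory=lambda: [
            "congestive_heart_failure",
            "cirrhosis",
            "end_stage_renal_disease",
        ]
    )
    hsct_unfit_age: int = 75

    @model_validator(mode="after")
    def _check(self) -> "StudyConfig":
        if self.gap_days <= 0:
            raise ConfigError("gap_days must be positive")
        if self.target_cost_year not in self.cpi_table:
            raise ConfigError(
                f"cpi_table missing target_cost_year {self.target_cost_year}"
            )
        for drug in CML_CP_DRUGS:
            if drug not in self.approval_dates:
                raise ConfigError(f"approval_dates missing entry for {drug}")
        if self.ip_cost_attribution not in ("prorate", "start"):
            raise ConfigError("ip_cost_attribution must be 'prorate' or 'start'")
        return self

    def dx_to_1l_window(self, payer: str) -> tuple[int, int]:
        """(days before, days after) first CML diagnosis within which 1L may start."""
        after = (
            self.dx_to_1l_after_days_medicare
            if payer == "medicare"
            else self.dx_to_1l_after_days_commercial
        )
        return self.dx_to_1l_before_days, after

    def cml_dx_codes(self, payer: str) -> list[str]:
        return (
            self.codes.cml_dx_medicare if payer == "medicare" else self.codes.cml_dx
        )

    # -- serialization ----------------------------------------------------

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(
                self.model_dump(mode="json"), fh, sort_keys=False, allow_unicode=True
            )

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path, "r", encoding="utf-8") as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.model_validate(payload)


def code_matches(code: str, prefixes: list[str] | tuple[str, ...]) -> bool:
    """Whether ``code`` matches any configured prefix (case-insensitive)."""
    c = code.strip().upper()
    return any(c.startswith(p.strip().upper()) for p in prefixes if p)


def any_code_matches(codes, prefixes) -> bool:
    return any(code_matches(c, prefixes) for c in codes)
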