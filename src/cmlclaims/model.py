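"""Claims data model: typed records, the in-memory bundle, enrollment merging.

A :class:`ClaimsBundle` holds four pandas DataFrames (pharmacy claims,
medical claims, enrollment spans, patient demographics) with fixed column
schemas.  All dates are whole calendar days (``datetime.date``; stored as
ISO-8601 strings on disk) and all intervals in the data model are closed:
an inpatient stay covers ``end - start + 1`` days, while gaps *between*
events span ``end - start`` days.

Multi-code fields (``diagnosis_codes``, ``procedure_codes``) are
semicolon-joined strings so the bundle round-trips through plain CSV/TSV.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, fields as dc_fields
from typing import Iterable, Optional

import pandas as pd

from .config import ALL_DRUGS, StudyConfig

PHARMACY_COLUMNS = [
    "patient_id", "fill_date", "drug", "days_supply", "paid_amount", "service_year",
]
MEDICAL_COLUMNS = [
    "patient_id", "start_date", "end_date", "setting",
    "diagnosis_codes", "procedure_codes", "paid_amount", "service_year",
]
ENROLLMENT_COLUMNS = ["patient_id", "start_date", "end_date", "plan_type", "hmo_flag"]
PATIENT_COLUMNS = ["patient_id", "birth_year", "sex", "region", "death_date", "payer"]

SETTINGS = ("inpatient", "outpatient", "emergency")


def join_codes(codes: Iterable[str]) -> str:
    return ";".join(c for c in codes if c)


def split_codes(value) -> list[str]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return []
    s = str(value).strip()
    return [c for c in s.split(";") if c] if s else []


@dataclass(frozen=True)
class PharmacyClaim:
    patient_id: str
    fill_date: dt.date
    drug: str
    days_supply: int
    paid_amount: float
    service_year: int


@dataclass(frozen=True)
class MedicalClaim:
    patient_id: str
    start_date: dt.date
    end_date: dt.date
    setting: str
    diagnosis_codes: tuple[str, ...]
    procedure_codes: tuple[str, ...]
    paid_amount: float
    service_year: int


@dataclass(frozen=True)
class EnrollmentSpan:
    patient_id: str
    start_date: dt.date
    end_date: dt.date
    plan_type: str = "ppo"
    hmo_flag: bool = False


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    birth_year: int
    sex: str
    region: str
    death_date: Optional[dt.date]
    payer: str


@dataclass
class ClaimsBundle:
    """One study population's claims tables, indexed by opaque patient ids."""

    pharmacy: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=PHARMACY_COLUMNS))
    medical: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=MEDICAL_COLUMNS))
    enrollment: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=ENROLLMENT_COLUMNS))
    patients: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=PATIENT_COLUMNS))

    def patient_ids(self) -> list[str]:
        ids: set[str] = set(self.patients["patient_id"])
        return sorted(ids)

    def sort(self) -> "ClaimsBundle":
        """Canonical row order; pipeline results never depend on input order."""
        self.pharmacy = self.pharmacy.sort_values(
            ["patient_id", "fill_date", "drug", "days_supply"], kind="mergesort"
        ).reset_index(drop=True)
        self.medical = self.medical.sort_values(
            ["patient_id", "start_date", "end_date", "setting"], kind="mergesort"
        ).reset_index(drop=True)
        self.enrollment = self.enrollment.sort_values(
            ["patient_id", "start_date", "end_date"], kind="mergesort"
        ).reset_index(drop=True)
        self.patients = self.patients.sort_values("patient_id", kind="mergesort").reset_index(drop=True)
        return self

    # Convenience constructors used by the simulator and tests.
    @classmethod
    def from_records(
        cls,
        pharmacy: Iterable[PharmacyClaim] = (),
        medical: Iterable[MedicalClaim] = (),
        enrollment: Iterable[EnrollmentSpan] = (),
        patients: Iterable[PatientRecord] = (),
    ) -> "ClaimsBundle":
        ph = pd.DataFrame(
            [vars(r) if not isinstance(r, PharmacyClaim) else
             {f.name: getattr(r, f.name) for f in dc_fields(r)} for r in pharmacy],
            columns=PHARMACY_COLUMNS,
        )
        med_rows = []
        for r in medical:
            med_rows.append(
                {
                    "patient_id": r.patient_id,
                    "start_date": r.start_date,
                    "end_date": r.end_date,
                    "setting": r.setting,
                    "diagnosis_codes": join_codes(r.diagnosis_codes),
                    "procedure_codes": join_codes(r.procedure_codes),
                    "paid_amount": r.paid_amount,
                    "service_year": r.service_year,
                }
            )
        med = pd.DataFrame(med_rows, columns=MEDICAL_COLUMNS)
        enr = pd.DataFrame(
            [{f.name: getattr(r, f.name) for f in dc_fields(r)} for r in enrollment],
            columns=ENROLLMENT_COLUMNS,
        )
        pat = pd.DataFrame(
            [{f.name: getattr(r, f.name) for f in dc_fields(r)} for r in patients],
            columns=PATIENT_COLUMNS,
        )
        return cls(pharmacy=ph, medical=med, enrollment=enr, patients=pat).sort()


def merge_enrollment(
    spans: list[EnrollmentSpan], allowable_gap_days: int = 0
) -> list[EnrollmentSpan]:
    """Merge one patient's enrollment spans into sorted disjoint coverage.

    Two spans merge when they overlap or when the number of uncovered days
    between them (``next.start - prev.end - 1`` with closed intervals) is at
    most ``allowable_gap_days``.  Merging is idempotent and independent of
    input order.  The merged span keeps the first span's plan type and flags
    HMO coverage if any constituent was HMO.
    """
    if not spans:
        return []
    pid = spans[0].patient_id
    if any(s.patient_id != pid for s in spans):
        raise ValueError("merge_enrollment expects spans for a single patient")
    ordered = sorted(spans, key=lambda s: (s.start_date, s.end_date))
    merged: list[EnrollmentSpan] = [ordered[0]]
    for s in ordered[1:]:
        last = merged[-1]
        uncovered = (s.start_date - last.end_date).days - 1
        if uncovered <= allowable_gap_days:
            merged[-1] = EnrollmentSpan(
                patient_id=pid,
                start_date=last.start_date,
                end_date=max(last.end_date, s.end_date),
                plan_type=last.plan_type,
                hmo_flag=last.hmo_flag or s.hmo_flag,
            )
        else:
            merged.append(s)
    return merged


def covers(spans: list[EnrollmentSpan], start: dt.date, end: dt.date) -> bool:
    """Whether some merged span fully covers the closed interval [start, end]."""
    return any(s.start_date <= start and s.end_date >= end for s in spans)


def span_containing(spans: list[EnrollmentSpan], day: dt.date) -> Optional[EnrollmentSpan]:
    for s in spans:
        if s.start_date <= day <= s.end_date:
            return s
    return None


def map_drug(raw_code: str, drug_map: dict[str, str]) -> str:
    """Map a raw drug code/name to a canonical token, defaulting to ``other``."""
    token = drug_map.get(str(raw_code).strip().lower(), "other")
    return token if token in ALL_DRUGS else "other"


def enrollment_spans_for(bundle: ClaimsBundle, patient_id: str) -> list[EnrollmentSpan]:
    df = bundle.enrollment
    sub = df[df["patient_id"] == patient_id]
    return [
        EnrollmentSpan(
            patient_id=patient_id,
            start_date=row.start_date,
            end_date=row.end_date,
            plan_type=row.plan_type,
            hmo_flag=bool(row.hmo_flag),
        )
        for row in sub.itertuples()
    ]


def validate_config_consistency(config: StudyConfig) -> None:
    """Hook for callers that build configs programmatically; re-runs model
    validation so invariants hold before any data is touched."""
    StudyConfig.model_validate(config.model_dump())
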