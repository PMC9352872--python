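"""Reading and writing claims bundles as delimited text tables.

Four UTF-8 delimited files (comma by default, tab accepted via a ``.tsv``
extension or explicit ``delimiter``) with header rows:

* pharmacy:   patient_id, fill_date, drug, days_supply, paid_amount, service_year
* medical:    patient_id, start_date, end_date, setting, diagnosis_codes,
              procedure_codes, paid_amount, service_year
* enrollment: patient_id, start_date, end_date, plan_type, hmo_flag
* patients:   patient_id, birth_year, sex, region, death_date, payer

Dates are ISO-8601 (``YYYY-MM-DD``); multi-code fields are
semicolon-joined.  Rows violating a type invariant (negative days supply,
end before start, service year disagreeing with the claim date, unknown
setting, unparseable date) are rejected individually and reported as
:class:`RowDiagnostic` entries with 1-based data line numbers; a missing
required column raises :class:`SchemaError` naming the column.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

from .config import StudyConfig
from .model import (
    ENROLLMENT_COLUMNS,
    MEDICAL_COLUMNS,
    PATIENT_COLUMNS,
    PHARMACY_COLUMNS,
    SETTINGS,
    ClaimsBundle,
    map_drug,
)

TABLE_COLUMNS = {
    "pharmacy": PHARMACY_COLUMNS,
    "medical": MEDICAL_COLUMNS,
    "enrollment": ENROLLMENT_COLUMNS,
    "patients": PATIENT_COLUMNS,
}


class SchemaError(ValueError):
    """A required column is missing from an input table."""


@dataclass(frozen=True)
class RowDiagnostic:
    table: str
    line: int  # 1-based data row number (header excluded)
    message: str


@dataclass
class ReadResult:
    bundle: ClaimsBundle
    diagnostics: list[RowDiagnostic]


def _delimiter_for(path: Path, delimiter: Optional[str]) -> str:
    if delimiter:
        return delimiter
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def _parse_date(value) -> dt.date:
    s = str(value).strip()
    return dt.date.fromisoformat(s)


def _parse_optional_date(value) -> Optional[dt.date]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    if not s or s.lower() in ("none", "nan", "na"):
        return None
    return dt.date.fromisoformat(s)


def _load_table(path: Path, table: str, delimiter: Optional[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_delimiter_for(path, delimiter), dtype=str, keep_default_na=False)
    missing = [c for c in TABLE_COLUMNS[table] if c not in df.columns]
    if missing:
        raise SchemaError(f"{table} table {path} missing required column(s): {', '.join(missing)}")
    return df


def read_claims_bundle(
    paths: Mapping[str, str | Path],
    schema: Optional[StudyConfig] = None,
    delimiter: Optional[str] = None,
) -> ReadResult:
    """Read and validate the four claims tables.

    ``paths`` maps table names (``pharmacy``, ``medical``, ``enrollment``,
    ``patients``) to file locations.  Returns the validated bundle plus
    row-level diagnostics for every rejected row.
    """
    schema = schema or StudyConfig()
    diagnostics: list[RowDiagnostic] = []

    def reject(table: str, line: int, message: str) -> None:
        diagnostics.append(RowDiagnostic(table=table, line=line, message=message))

    # pharmacy ------------------------------------------------------------
    ph_rows = []
    df = _load_table(Path(paths["pharmacy"]), "pharmacy", delimiter)
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            fill_date = _parse_date(row.fill_date)
        except ValueError:
            reject("pharmacy", i, f"unparseable fill_date {row.fill_date!r}")
            continue
        try:
            days_supply = int(row.days_supply)
            paid = float(row.paid_amount)
            year = int(row.service_year)
        except ValueError as exc:
            reject("pharmacy", i, f"unparseable numeric field: {exc}")
            continue
        if days_supply < 0:
            reject("pharmacy", i, f"days_supply {days_supply} < 0")
            continue
        if paid < 0:
            reject("pharmacy", i, f"paid_amount {paid} < 0")
            continue
        if year != fill_date.year:
            reject("pharmacy", i, f"service_year {year} != year of fill_date {fill_date}")
            continue
        ph_rows.append(
            {
                "patient_id": str(row.patient_id),
                "fill_date": fill_date,
                "drug": map_drug(row.drug, schema.drug_map),
                "days_supply": days_supply,
                "paid_amount": paid,
                "service_year": year,
            }
        )

    # medical -------------------------------------------------------------
    med_rows = []
    df = _load_table(Path(paths["medical"]), "medical", delimiter)
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            start = _parse_date(row.start_date)
            end = _parse_date(row.end_date)
        except ValueError as exc:
            reject("medical", i, f"unparseable date: {exc}")
            continue
        try:
            paid = float(row.paid_amount)
            year = int(row.service_year)
        except ValueError as exc:
            reject("medical", i, f"unparseable numeric field: {exc}")
            continue
        setting = str(row.setting).strip().lower()
        if setting not in SETTINGS:
            reject("medical", i, f"unknown setting {row.setting!r}")
            continue
        if end < start:
            reject("medical", i, f"end_date {end} before start_date {start}")
            continue
        if setting != "inpatient" and end != start:
            reject("medical", i, f"{setting} claim may not span multiple days")
            continue
        if paid < 0:
            reject("medical", i, f"paid_amount {paid} < 0")
            continue
        if year != start.year:
            reject("medical", i, f"service_year {year} != year of start_date {start}")
            continue
        med_rows.append(
            {
                "patient_id": str(row.patient_id),
                "start_date": start,
                "end_date": end,
                "setting": setting,
                "diagnosis_codes": str(row.diagnosis_codes),
                "procedure_codes": str(row.procedure_codes),
                "paid_amount": paid,
                "service_year": year,
            }
        )

    # enrollment ----------------------------------------------------------
    enr_rows = []
    df = _load_table(Path(paths["enrollment"]), "enrollment", delimiter)
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            start = _parse_date(row.start_date)
            end = _parse_date(row.end_date)
        except ValueError as exc:
            reject("enrollment", i, f"unparseable date: {exc}")
            continue
        if end < start:
            reject("enrollment", i, f"end_date {end} before start_date {start}")
            continue
        enr_rows.append(
            {
                "patient_id": str(row.patient_id),
                "start_date": start,
                "end_date": end,
                "plan_type": str(row.plan_type),
                "hmo_flag": str(row.hmo_flag).strip().lower() in ("1", "true", "yes"),
            }
        )

    # patients ------------------------------------------------------------
    pat_rows = []
    df = _load_table(Path(paths["patients"]), "patients", delimiter)
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            birth_year = int(row.birth_year)
        except ValueError:
            reject("patients", i, f"unparseable birth_year {row.birth_year!r}")
            continue
        try:
            death = _parse_optional_date(row.death_date)
        except ValueError:
            reject("patients", i, f"unparseable death_date {row.death_date!r}")
            continue
        pat_rows.append(
            {
                "patient_id": str(row.patient_id),
                "birth_year": birth_year,
                "sex": str(row.sex),
                "region": str(row.region),
                "death_date": death,
                "payer": str(row.payer).strip().lower(),
            }
        )

    bundle = ClaimsBundle(
        pharmacy=pd.DataFrame(ph_rows, columns=PHARMACY_COLUMNS),
        medical=pd.DataFrame(med_rows, columns=MEDICAL_COLUMNS),
        enrollment=pd.DataFrame(enr_rows, columns=ENROLLMENT_COLUMNS),
        patients=pd.DataFrame(pat_rows, columns=PATIENT_COLUMNS),
    ).sort()
    return ReadResult(bundle=bundle, diagnostics=diagnostics)


def write_claims_bundle(
    bundle: ClaimsBundle, out_dir: str | Path, delimiter: str = ","
) -> dict[str, Path]:
    """Write the four tables under ``out_dir``; returns the file map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ext = ".tsv" if delimiter == "\t" else ".csv"
    paths: dict[str, Path] = {}
    for table in TABLE_COLUMNS:
        df = getattr(bundle, table).copy()
        for col in df.columns:
            if col.endswith("_date"):
                df[col] = df[col].map(lambda d: d.isoformat() if d is not None else "")
        if table == "enrollment":
            df["hmo_flag"] = df["hmo_flag"].map(lambda b: "1" if b else "0")
        path = out / f"{table}{ext}"
        df.to_csv(path, sep=delimiter, index=False)
        paths[table] = path
    return paths
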