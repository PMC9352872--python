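"""Healthcare costs: PPPM by component, CPI inflation, HSCT event costing.

Costs are taken from the payer's perspective (plan-paid amounts), inflated
from service-year to target-year dollars with the medical-care component of
the consumer price index (one factor per calendar year), and reported per
patient per month (PPPM; month = 365.25/12 days) over the 3L+, 3L and 4L
windows.

Components: pharmacy (fills attributed wholly to the fill date), inpatient
(paid amounts pro-rated linearly by the fraction of stay days inside the
window, switchable to whole-amount-at-admission attribution), outpatient and
emergency (single-day claims attributed to their service date).  Per patient
the components sum to the total by construction.  CML-related medical costs
are claims with a CML diagnosis or an omacetaxine procedure code;
CML-related pharmacy costs are fills for one of the five TKIs (omacetaxine
pharmacy fills are all-cause only).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .config import TKI_DRUGS, ConfigError, StudyConfig, any_code_matches
from .cohort import PatientSelection
from .hru import PERIOD_LABELS, PeriodWindow, is_cml_related, merge_ip_stays, period_window
from .model import split_codes

COMPONENTS = ("pharmacy", "ip", "op", "ed")


def inflate(
    amount: float,
    service_year: int,
    cpi_table: dict[int, float],
    target_year: int,
) -> float:
    """Express ``amount`` (service-year USD) in target-year USD."""
    for year in (service_year, target_year):
        if year not in cpi_table:
            raise ConfigError(f"cpi_table missing year {year}")
    return amount * cpi_table[target_year] / cpi_table[service_year]


@dataclass(frozen=True)
class HSCTEvent:
    """One transplant: the procedure date, its admission, its total cost."""

    patient_id: str
    procedure_date: dt.date
    admission_start: dt.date
    admission_end: dt.date
    cost: float  # target-year USD, all claims within the admission
    no_admission: bool = False  # fallback: procedure claim had no containing stay


def find_hsct_events(
    medical: pd.DataFrame, config: StudyConfig
) -> list[HSCTEvent]:
    """Locate HSCT procedures for one patient and cost their admissions.

    The event cost is the sum of inflated paid amounts of every inpatient
    claim within the merged inpatient stay containing the procedure date.
    A procedure with no containing admission is costed from the procedure
    claim alone and flagged.
    """
    proc_rows = [
        row
        for row in medical.itertuples()
        if any_code_matches(split_codes(row.procedure_codes), config.codes.hsct_procedures)
    ]
    if not proc_rows:
        return []
    ip_rows = [row for row in medical.itertuples() if row.setting == "inpatient"]
    stays = merge_ip_stays([(r.start_date, r.end_date) for r in ip_rows])
    events = []
    for proc in proc_rows:
        stay = next((s for s in stays if s[0] <= proc.start_date <= s[1]), None)
        if stay is None:
            events.append(
                HSCTEvent(
                    patient_id=proc.patient_id,
                    procedure_date=proc.start_date,
                    admission_start=proc.start_date,
                    admission_end=proc.end_date,
                    cost=inflate(
                        proc.paid_amount, proc.service_year, config.cpi_table,
                        config.target_cost_year,
                    ),
                    no_admission=True,
                )
            )
            continue
        cost = sum(
            inflate(r.paid_amount, r.service_year, config.cpi_table, config.target_cost_year)
            for r in ip_rows
            if r.start_date >= stay[0] and r.end_date <= stay[1]
        )
        events.append(
            HSCTEvent(
                patient_id=proc.patient_id,
                procedure_date=proc.start_date,
                admission_start=stay[0],
                admission_end=stay[1],
                cost=cost,
            )
        )
    return events


def _claim_in_hsct_admission(row, events: list[HSCTEvent]) -> bool:
    return any(
        e.admission_start <= row.start_date and row.end_date <= e.admission_end
        for e in events
        if not e.no_admission
    ) or any(
        e.no_admission and row.start_date == e.procedure_date for e in events
    )


def component_costs(
    pharmacy: pd.DataFrame,
    medical: pd.DataFrame,
    window: PeriodWindow,
    config: StudyConfig,
    cml_related: bool = False,
    exclude_hsct: Optional[list[HSCTEvent]] = None,
) -> dict[str, float]:
    """Inflated per-patient component totals inside ``window``.

    With ``exclude_hsct`` given, claims attributed to those transplant
    admissions are removed (the HSCT-exclusion sensitivity analysis).
    """
    start, end = window.start, window.end
    out = {c: 0.0 for c in COMPONENTS}

    for row in pharmacy.itertuples():
        if not (start <= row.fill_date < end):
            continue
        if cml_related and row.drug not in TKI_DRUGS:
            continue
        out["pharmacy"] += inflate(
            row.paid_amount, row.service_year, config.cpi_table, config.target_cost_year
        )

    for row in medical.itertuples():
        if cml_related and not is_cml_related(
            split_codes(row.diagnosis_codes), split_codes(row.procedure_codes), config
        ):
            continue
        if exclude_hsct and row.setting == "inpatient" and _claim_in_hsct_admission(row, exclude_hsct):
            continue
        paid = inflate(
            row.paid_amount, row.service_year, config.cpi_table, config.target_cost_year
        )
        if row.setting == "inpatient":
            total_days = (row.end_date - row.start_date).days + 1
            clip_start = max(row.start_date, start)
            clip_end = min(row.end_date, end - dt.timedelta(days=1))
            inside = max(0, (clip_end - clip_start).days + 1)
            if inside == 0:
                continue
            if config.ip_cost_attribution == "prorate":
                out["ip"] += paid * inside / total_days
            else:  # "start": whole amount to the window containing admission
                if start <= row.start_date < end:
                    out["ip"] += paid
        elif row.setting == "outpatient":
            if start <= row.start_date < end:
                out["op"] += paid
        elif row.setting == "emergency":
            if start <= row.start_date < end:
                out["ed"] += paid
    out["total"] = sum(out[c] for c in COMPONENTS)
    return out


def pppm(
    per_patient_costs: list[float],
    per_patient_person_days: list[int],
    month_length_days: float = 365.25 / 12,
) -> tuple[np.ndarray, dict[str, float]]:
    """Per-patient PPPM vector and its mean/SD/median.

    Patients with zero person-days carry no rate information and are
    excluded from the vector.
    """
    vals = [
        cost / (days / month_length_days)
        for cost, days in zip(per_patient_costs, per_patient_person_days)
        if days > 0
    ]
    arr = np.array(vals, dtype=float)
    if arr.size == 0:
        return arr, {"mean": float("nan"), "sd": float("nan"), "median": float("nan")}
    stats = {
        "mean": float(arr.mean()),
        "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        "median": float(np.median(arr)),
    }
    return arr, stats


def cost_summary(
    pharmacy_by_patient: dict[str, pd.DataFrame],
    medical_by_patient: dict[str, pd.DataFrame],
    selections: dict[str, PatientSelection],
    cohort_ids: list[str],
    config: StudyConfig,
    exclude_hsct: bool = False,
) -> pd.DataFrame:
    """PPPM cost table: rows per (period, cause, component) with
    mean/SD/median over cohort members contributing person-time.

    With ``exclude_hsct`` the claims of every HSCT admission are removed
    first (sensitivity analysis); with no transplants in the cohort the
    result equals the main analysis.
    """
    empty_ph = next(iter(pharmacy_by_patient.values())).iloc[0:0] if pharmacy_by_patient else pd.DataFrame()
    empty_med = next(iter(medical_by_patient.values())).iloc[0:0] if medical_by_patient else pd.DataFrame()
    hsct_events: dict[str, list[HSCTEvent]] = {}
    if exclude_hsct:
        for pid in cohort_ids:
            med = medical_by_patient.get(pid, empty_med)
            ev = find_hsct_events(med, config)
            if ev:
                hsct_events[pid] = ev

    rows = []
    for label in PERIOD_LABELS:
        windows = [
            w
            for pid in sorted(cohort_ids)
            if (w := period_window(selections[pid], label)) is not None
            and w.person_days > 0
        ]
        for cause in ("all_cause", "cml_related"):
            comp_values: dict[str, list[float]] = {c: [] for c in (*COMPONENTS, "total")}
            days = []
            for w in windows:
                costs = component_costs(
                    pharmacy_by_patient.get(w.patient_id, empty_ph),
                    medical_by_patient.get(w.patient_id, empty_med),
                    w,
                    config,
                    cml_related=(cause == "cml_related"),
                    exclude_hsct=hsct_events.get(w.patient_id),
                )
                for c in (*COMPONENTS, "total"):
                    comp_values[c].append(costs[c])
                days.append(w.person_days)
            for c in (*COMPONENTS, "total"):
                _, stats = pppm(comp_values[c], days, config.month_length_days)
                rows.append(
                    {
                        "period": label,
                        "cause": cause,
                        "component": c,
                        "n_patients": len(windows),
                        "pppm_mean": stats["mean"],
                        "pppm_sd": stats["sd"],
                        "pppm_median": stats["median"],
                        "hsct_included": not exclude_hsct,
                    }
                )
    return pd.DataFrame(rows)


def hsct_event_table(
    medical_by_patient: dict[str, pd.DataFrame],
    cohort_ids: list[str],
    config: StudyConfig,
) -> pd.DataFrame:
    """Event-level HSCT costs (target-year USD) across the cohort."""
    rows = []
    for pid in sorted(cohort_ids):
        med = medical_by_patient.get(pid)
        if med is None:
            continue
        for e in find_hsct_events(med, config):
            rows.append(
                {
                    "patient_id": pid,
                    "procedure_date": e.procedure_date,
                    "admission_start": e.admission_start,
                    "admission_end": e.admission_end,
                    "cost": e.cost,
                    "no_admission": e.no_admission,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id", "procedure_date", "admission_start", "admission_end",
            "cost", "no_admission",
        ],
    )
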