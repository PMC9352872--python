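"""Healthcare resource utilization: annual incidence rates over 3L+/3L/4L.

Four measures are counted per analysis window: inpatient admissions
(overlapping inpatient claims merged into single stays), inpatient days
(stay days clipped to the window), days with outpatient services (distinct
calendar dates with at least one outpatient claim) and emergency-department
visits (distinct dates with an ED claim).  A claim is CML-related when it
bears a CML diagnosis code in any position or an omacetaxine procedure
code.

Analysis windows are half-open day intervals [start, end): person-days =
``end - start``, and a day ``d`` is inside iff ``start <= d < end``.
Annual incidence rates are cohort-aggregate: total events over total
person-days, times 365.25.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .config import StudyConfig, any_code_matches
from .cohort import PatientSelection
from .lines import TherapyLine
from .model import split_codes

MEASURES = ("ip_admissions", "ip_days", "op_days", "ed_visits")
PERIOD_LABELS = ("3L+", "3L", "4L")


@dataclass(frozen=True)
class PeriodWindow:
    """One patient's analysis window; ``person_days = (end - start).days``."""

    patient_id: str
    label: str
    start: dt.date
    end: dt.date

    @property
    def person_days(self) -> int:
        return (self.end - self.start).days


def period_window(
    sel: PatientSelection, label: str
) -> Optional[PeriodWindow]:
    """The 3L+/3L/4L window for one cohort member, clipped to follow-up.

    3L+ is the whole follow-up; 3L runs from 3L start to the earlier of 3L
    end and follow-up end; 4L analogously (absent when the patient never
    reached a fourth line).
    """
    if sel.index_date is None or sel.follow_up_end is None:
        return None
    fu_start, fu_end = sel.follow_up_start, sel.follow_up_end
    if label == "3L+":
        return PeriodWindow(sel.patient_id, label, fu_start, fu_end)
    line_no = 3 if label == "3L" else 4
    if len(sel.lines) < line_no:
        return None
    ln: TherapyLine = sel.lines[line_no - 1]
    start = max(ln.start_date, fu_start)
    end = min(ln.end_date, fu_end)
    if end < start:
        end = start
    return PeriodWindow(sel.patient_id, label, start, end)


def merge_ip_stays(claims: list[tuple[dt.date, dt.date]]) -> list[tuple[dt.date, dt.date]]:
    """Merge overlapping/abutting inpatient claim spans into admissions."""
    if not claims:
        return []
    ordered = sorted(claims)
    stays = [ordered[0]]
    for s, e in ordered[1:]:
        ls, le = stays[-1]
        if s <= le + dt.timedelta(days=1):
            stays[-1] = (ls, max(le, e))
        else:
            stays.append((s, e))
    return stays


def is_cml_related(dx_codes: list[str], proc_codes: list[str], config: StudyConfig) -> bool:
    return any_code_matches(dx_codes, config.codes.cml_dx) or any_code_matches(
        proc_codes, config.codes.omacetaxine_procedures
    )


def count_hru(
    medical: pd.DataFrame,
    window: PeriodWindow,
    config: StudyConfig,
    cml_related: bool = False,
) -> dict[str, int]:
    """Measure counts for one patient's medical claims inside ``window``."""
    start, end = window.start, window.end
    ip_spans: list[tuple[dt.date, dt.date]] = []
    op_dates: set[dt.date] = set()
    ed_dates: set[dt.date] = set()
    for row in medical.itertuples():
        if cml_related and not is_cml_related(
            split_codes(row.diagnosis_codes), split_codes(row.procedure_codes), config
        ):
            continue
        if row.setting == "inpatient":
            if row.end_date >= start and row.start_date < end:
                ip_spans.append((row.start_date, row.end_date))
        elif row.setting == "outpatient":
            if start <= row.start_date < end:
                op_dates.add(row.start_date)
        elif row.setting == "emergency":
            if start <= row.start_date < end:
                ed_dates.add(row.start_date)
    stays = merge_ip_stays(ip_spans)
    admissions = 0
    ip_days = 0
    for s, e in stays:
        clip_start = max(s, start)
        clip_end = min(e, end - dt.timedelta(days=1))  # closed stay vs half-open window
        if clip_end >= clip_start:
            admissions += 1
            ip_days += (clip_end - clip_start).days + 1
    return {
        "ip_admissions": admissions,
        "ip_days": ip_days,
        "op_days": len(op_dates),
        "ed_visits": len(ed_dates),
    }


def annual_rate(
    count: int, person_days: float, year_length_days: float = 365.25
) -> Optional[float]:
    """Events per person-year; absent (None), not zero, when there is no
    person-time."""
    if person_days <= 0:
        return None
    return count / person_days * year_length_days


def hru_summary(
    medical_by_patient: dict[str, pd.DataFrame],
    selections: dict[str, PatientSelection],
    cohort_ids: list[str],
    config: StudyConfig,
) -> pd.DataFrame:
    """Cohort HRU table: one row per (period, cause, measure).

    Columns: period, cause, measure, events, person_days, annual_rate.
    """
    rows = []
    empty = next(iter(medical_by_patient.values())).iloc[0:0] if medical_by_patient else pd.DataFrame()
    for label in PERIOD_LABELS:
        windows = [
            w
            for pid in sorted(cohort_ids)
            if (w := period_window(selections[pid], label)) is not None
        ]
        person_days = sum(w.person_days for w in windows)
        for cause in ("all_cause", "cml_related"):
            totals = {m: 0 for m in MEASURES}
            for w in windows:
                med = medical_by_patient.get(w.patient_id, empty)
                counts = count_hru(med, w, config, cml_related=(cause == "cml_related"))
                for m in MEASURES:
                    totals[m] += counts[m]
            for m in MEASURES:
                rows.append(
                    {
                        "period": label,
                        "cause": cause,
                        "measure": m,
                        "events": totals[m],
                        "person_days": person_days,
                        "annual_rate": annual_rate(
                            totals[m], person_days, config.year_length_days
                        ),
                    }
                )
    return pd.DataFrame(rows)
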