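"""Patient-selection cascade, index dates and follow-up definition.

The analytic cohort is built by applying, in a fixed order, the selection
criteria of the study design: at least one CML diagnosis (payer-appropriate
code list), adult at first-line start, an approved first-line drug, 1L
initiation within the allowed window around the first diagnosis, a clean
>=6-month washout, continuous enrollment from the washout through 12 months
after diagnosis (waived for Medicare decedents), no HMO coverage
(Medicare), no remission/relapse code on/before 1L start, no clinical-trial
claim on/before the index date, and finally reaching a third line of
therapy.  The index date is the start of the third line; follow-up runs
from the index to the earliest of end of data, end of continuous
enrollment, HSCT, or non-listed (AP/BC) chemotherapy.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .config import (
    CML_CP_DRUGS,
    FIRST_LINE_ELIGIBLE_DRUGS,
    StudyConfig,
    any_code_matches,
)
from .lines import TherapyLine, build_lines, collect_therapy_events
from .model import (
    ClaimsBundle,
    EnrollmentSpan,
    covers,
    merge_enrollment,
    span_containing,
    split_codes,
)

CRITERIA_LABELS = [
    "1+ CML diagnosis",
    "Adult (>=18) at 1L initiation",
    "Approved 1L CML-CP drug",
    "1L within window around first CML diagnosis",
    "Clean washout (no prior CML-CP therapy, continuous enrollment)",
    "Continuous enrollment through 12 months post-diagnosis",
    "No HMO coverage during continuous enrollment (Medicare)",
    "No remission/relapse code on/before 1L start",
    "No clinical-trial claim on/before index",
    "Reached 3L",
]


@dataclass
class AttritionTable:
    """Ordered cascade counts: (criterion label, n remaining, n excluded)."""

    rows: list[tuple[str, int, int]]
    cohort_ids: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["criterion", "n_remaining", "n_excluded"])


@dataclass
class PatientSelection:
    """Everything selection learned about one patient, reused downstream."""

    patient_id: str
    payer: str
    first_cml_dx_date: Optional[dt.date] = None
    lines: list[TherapyLine] = field(default_factory=list)
    observation_end: Optional[dt.date] = None
    enrollment_end: Optional[dt.date] = None
    index_date: Optional[dt.date] = None
    baseline_start: Optional[dt.date] = None
    baseline_end: Optional[dt.date] = None
    follow_up_start: Optional[dt.date] = None
    follow_up_end: Optional[dt.date] = None
    excluded_at: Optional[str] = None

    @property
    def line1_start(self) -> Optional[dt.date]:
        return self.lines[0].start_date if self.lines else None


@dataclass
class SelectionResult:
    attrition: AttritionTable
    patients: dict[str, PatientSelection]

    @property
    def cohort_ids(self) -> list[str]:
        return self.attrition.cohort_ids


def first_cml_diagnosis(medical: pd.DataFrame, cml_dx_codes: list[str]) -> Optional[dt.date]:
    """Earliest medical-claim start date bearing any configured CML code."""
    best: Optional[dt.date] = None
    for row in medical.itertuples():
        if any_code_matches(split_codes(row.diagnosis_codes), cml_dx_codes):
            if best is None or row.start_date < best:
                best = row.start_date
    return best


def check_washout(
    pharmacy: pd.DataFrame,
    medical: pd.DataFrame,
    line1_start: dt.date,
    washout_days: int,
    merged_spans: list[EnrollmentSpan],
    config: StudyConfig,
) -> bool:
    """True iff enrollment covers the washout window and it is free of
    CML-CP therapy.

    The window is the ``washout_days`` days before 1L start, i.e. the
    closed interval [line1_start - washout_days, line1_start - 1].
    Hydroxyurea is a pretreatment, never line therapy, so its fills do not
    violate the washout.
    """
    w_start = line1_start - dt.timedelta(days=washout_days)
    w_end = line1_start - dt.timedelta(days=1)
    if not covers(merged_spans, w_start, w_end):
        return False
    for row in pharmacy.itertuples():
        if row.drug in CML_CP_DRUGS and w_start <= row.fill_date <= w_end:
            return False
    oma = config.codes.omacetaxine_procedures
    for row in medical.itertuples():
        if w_start <= row.start_date <= w_end and any_code_matches(
            split_codes(row.procedure_codes), oma
        ):
            return False
    return True


def define_follow_up(
    index_date: dt.date,
    enrollment_end: dt.date,
    data_end: dt.date,
    hsct_date: Optional[dt.date] = None,
    apbc_date: Optional[dt.date] = None,
) -> tuple[dt.date, dt.date]:
    """Follow-up window [index, min(data end, enrollment end, HSCT, AP/BC)].

    A zero-length window is allowed; an index after every candidate end is
    a construction defect and raises.
    """
    candidates = [enrollment_end, data_end]
    if hsct_date is not None:
        candidates.append(hsct_date)
    if apbc_date is not None:
        candidates.append(apbc_date)
    end = min(candidates)
    if end < index_date:
        raise ValueError(
            f"follow-up end {end} precedes index {index_date}; "
            "should be impossible by construction"
        )
    return index_date, end


def _observation_end(
    merged: list[EnrollmentSpan],
    anchor: dt.date,
    data_end: dt.date,
    death_date: Optional[dt.date],
) -> tuple[Optional[dt.date], Optional[dt.date]]:
    """(observation end, enrollment end) from the merged span containing
    ``anchor`` (the first therapy event or first diagnosis)."""
    span = span_containing(merged, anchor)
    if span is None:
        return None, None
    enrollment_end = min(span.end_date, data_end)
    obs_end = enrollment_end
    if death_date is not None:
        obs_end = min(obs_end, death_date)
    return obs_end, enrollment_end


def apply_selection(bundle: ClaimsBundle, config: StudyConfig) -> SelectionResult:
    """Run the selection cascade over every patient in the bundle.

    Returns the attrition table (monotone counts; per-step exclusions plus
    the final cohort sum to the input count) and per-patient selection
    state including constructed lines, index dates and follow-up windows
    for cohort members.
    """
    ph_groups = dict(tuple(bundle.pharmacy.groupby("patient_id", sort=True)))
    med_groups = dict(tuple(bundle.medical.groupby("patient_id", sort=True)))
    empty_ph = bundle.pharmacy.iloc[0:0]
    empty_med = bundle.medical.iloc[0:0]

    patients: dict[str, PatientSelection] = {}
    order = sorted(bundle.patients["patient_id"])
    pat_rows = {r.patient_id: r for r in bundle.patients.itertuples()}

    excluded_counts = {label: 0 for label in CRITERIA_LABELS}
    survivors: list[str] = []

    for pid in order:
        prow = pat_rows[pid]
        payer = prow.payer
        sel = PatientSelection(patient_id=pid, payer=payer)
        patients[pid] = sel
        ph = ph_groups.get(pid, empty_ph)
        med = med_groups.get(pid, empty_med)
        raw_spans = [
            EnrollmentSpan(pid, r.start_date, r.end_date, r.plan_type, bool(r.hmo_flag))
            for r in bundle.enrollment[bundle.enrollment["patient_id"] == pid].itertuples()
        ]
        merged = merge_enrollment(raw_spans, config.enrollment_merge_gap_days)
        death = prow.death_date

        def exclude(label: str) -> None:
            sel.excluded_at = label
            excluded_counts[label] += 1

        # (1) at least one CML diagnosis
        dx = first_cml_diagnosis(med, config.cml_dx_codes(payer))
        sel.first_cml_dx_date = dx
        if dx is None:
            exclude(CRITERIA_LABELS[0])
            continue

        # Build lines once (needed by almost every later criterion).
        events = collect_therapy_events((ph, med), config)
        if events:
            obs_end, enr_end = _observation_end(
                merged, events[0].date, config.data_end, death
            )
        else:
            obs_end = enr_end = None
        if obs_end is not None:
            sel.observation_end = obs_end
            sel.enrollment_end = enr_end
            sel.lines = build_lines(events, obs_end, config.gap_days)

        # (2) adult at 1L
        l1 = sel.line1_start
        if l1 is None or (l1.year - prow.birth_year) < 18:
            exclude(CRITERIA_LABELS[1])
            continue

        # (3) eligible, approved 1L drug.  Pre-approval fills were already
        # dropped when collecting events, so line 1 necessarily starts
        # on/after its drug's approval; the drug itself must be one of the
        # four 1L-eligible TKIs.
        if sel.lines[0].drug not in FIRST_LINE_ELIGIBLE_DRUGS:
            exclude(CRITERIA_LABELS[2])
            continue

        # (4) 1L within the window around first diagnosis
        before, after = config.dx_to_1l_window(payer)
        if not (dx - dt.timedelta(days=before) <= l1 <= dx + dt.timedelta(days=after)):
            exclude(CRITERIA_LABELS[3])
            continue

        # (5) clean washout
        if not check_washout(ph, med, l1, config.washout_days, merged, config):
            exclude(CRITERIA_LABELS[4])
            continue

        # (6) continuous enrollment from washout start through dx + 365 days
        w_start = l1 - dt.timedelta(days=config.washout_days)
        post_end = dx + dt.timedelta(days=config.post_dx_enrollment_days)
        waived = (
            payer == "medicare" and death is not None and death <= post_end
        )
        required_end = min(post_end, death) if waived else post_end
        if not covers(merged, w_start, required_end):
            exclude(CRITERIA_LABELS[5])
            continue

        # (7) no HMO coverage during the continuous-enrollment interval
        if payer == "medicare":
            hmo = any(
                s.hmo_flag
                and s.start_date <= required_end
                and s.end_date >= w_start
                for s in raw_spans
            )
            if hmo:
                exclude(CRITERIA_LABELS[6])
                continue

        # (8) no remission/relapse code on/before 1L start
        rem_rel = config.codes.cml_remission + config.codes.cml_relapse
        bad = any(
            row.start_date <= l1
            and any_code_matches(split_codes(row.diagnosis_codes), rem_rel)
            for row in med.itertuples()
        )
        if bad:
            exclude(CRITERIA_LABELS[7])
            continue

        # (9) no clinical-trial claim on/before index (3L start).  Patients
        # without a third line have no index date; the criterion is
        # vacuously satisfied and they fall out at step (10).
        index = sel.lines[2].start_date if len(sel.lines) >= 3 else None
        if index is not None:
            trial = any(
                row.start_date <= index
                and any_code_matches(
                    split_codes(row.diagnosis_codes), config.codes.clinical_trial
                )
                for row in med.itertuples()
            )
            if trial:
                exclude(CRITERIA_LABELS[8])
                continue

        # (10) reached 3L
        if index is None:
            exclude(CRITERIA_LABELS[9])
            continue

        sel.index_date = index
        sel.baseline_start = index - dt.timedelta(days=config.baseline_days)
        sel.baseline_end = index - dt.timedelta(days=1)
        hsct_date = next(
            (ln.end_date for ln in sel.lines if ln.end_event == "hsct"), None
        )
        apbc_date = next(
            (ln.end_date for ln in sel.lines if ln.end_event == "apbc_chemo"), None
        )
        sel.follow_up_start, sel.follow_up_end = define_follow_up(
            index, sel.enrollment_end, config.data_end, hsct_date, apbc_date
        )
        survivors.append(pid)

    # Assemble the attrition cascade.
    n = len(order)
    rows: list[tuple[str, int, int]] = [("All patients", n, 0)]
    remaining = n
    for label in CRITERIA_LABELS:
        excluded = excluded_counts[label]
        remaining -= excluded
        rows.append((label, remaining, excluded))
    attrition = AttritionTable(rows=rows, cohort_ids=sorted(survivors))
    return SelectionResult(attrition=attrition, patients=patients)
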