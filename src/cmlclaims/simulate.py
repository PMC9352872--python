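"""Synthetic longitudinal claims generator with known ground truth.

Emulates the structure of an administrative claims extract for a CML
population: multi-year enrollment spans, 30-day TKI fill cadence with
refill jitter and >=90-day treatment interruptions, drug switches with
short treatment-free windows, terminal HSCT and AP/BC-progression events,
Poisson background inpatient/outpatient/ED utilization with CML and
non-CML diagnoses, and gamma-distributed paid amounts expressed in
service-year dollars.  Every patient's *true* treatment trajectory (line
boundaries, end events, interruption gaps, period person-time and
per-period costs) is recorded alongside the claims, so the line-of-therapy
builder and every downstream outcome can be checked against ground truth.

Default calibration follows the commercially insured study conditions:
line-duration medians 8.47 / 4.24 / 8.32 months for 1L/2L/3L, ~9.2% of
first-line initiators reaching 3L, background annual rates of 0.4
inpatient admissions (mean stay 8.5 days, hence 3.4 inpatient days), 30.8
outpatient-service days and 1.2 ED visits per person-year, and an ~83%
CML-related share of inpatient stays.  Cost levels are plausible rather
than actuarially calibrated.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .config import (
    CML_CP_DRUGS,
    FIRST_LINE_ELIGIBLE_DRUGS,
    ConfigError,
    StudyConfig,
)
from .model import (
    ClaimsBundle,
    ENROLLMENT_COLUMNS,
    MEDICAL_COLUMNS,
    PATIENT_COLUMNS,
    PHARMACY_COLUMNS,
    EnrollmentSpan,
    merge_enrollment,
    span_containing,
)

_DAY = dt.timedelta(days=1)


class HRURates(BaseModel):
    """Annual background utilization rates (events per person-year)."""

    ip_admissions: float = 0.4
    ip_los_mean: float = 8.5  # mean length of stay, days
    op_days: float = 30.8
    ed_visits: float = 1.2
    cml_frac_ip: float = 0.831
    cml_frac_op: float = 0.75
    cml_frac_ed: float = 0.5

    @model_validator(mode="after")
    def _check(self) -> "HRURates":
        vals = [self.ip_admissions, self.op_days, self.ed_visits, self.ip_los_mean]
        if any(v < 0 for v in vals):
            raise ConfigError("HRU rates must be non-negative")
        return self


class GammaCost(BaseModel):
    shape: float
    mean: float  # target-year dollars

    @property
    def scale(self) -> float:
        return self.mean / self.shape


class CostModel(BaseModel):
    pharmacy_fill: GammaCost = GammaCost(shape=25.0, mean=9000.0)
    hydroxyurea_fill: GammaCost = GammaCost(shape=4.0, mean=150.0)
    other_fill: GammaCost = GammaCost(shape=4.0, mean=200.0)
    ip_day: GammaCost = GammaCost(shape=4.0, mean=5000.0)
    op_visit: GammaCost = GammaCost(shape=2.0, mean=500.0)
    ed_visit: GammaCost = GammaCost(shape=2.0, mean=1500.0)
    hsct_admission: GammaCost = GammaCost(shape=10.0, mean=220000.0)


class TrajectorySpec(BaseModel):
    """Parameters of the simulated study population."""

    n_patients: int = 500
    payer: str = "commercial"
    seed: int = 0

    # Distribution of the number of true lines per 1L initiator.
    line_count_distribution: dict[int, float] = Field(
        default_factory=lambda: {
            1: 0.7050, 2: 0.2034, 3: 0.0659, 4: 0.0182, 5: 0.0044, 6: 0.0031,
        }
    )
    first_line_drug_distribution: dict[str, float] = Field(
        default_factory=lambda: {"imatinib": 0.649, "dasatinib": 0.216, "nilotinib": 0.135}
    )
    # Preference weights for the next drug after a switch; the realized
    # transition matrix row excludes the current drug and renormalizes, so
    # its diagonal is zero by construction.
    transition_weights: dict[str, float] = Field(
        default_factory=lambda: {
            "imatinib": 0.15, "dasatinib": 0.40, "nilotinib": 0.29,
            "bosutinib": 0.11, "ponatinib": 0.04, "omacetaxine": 0.01,
        }
    )
    # Lognormal true line durations, by line number (last entry reused).
    line_duration_median_months: list[float] = Field(
        default_factory=lambda: [8.47, 4.24, 8.32, 8.39]
    )
    line_duration_sigma: list[float] = Field(
        default_factory=lambda: [1.06, 1.33, 1.12, 1.04]
    )
    fill_cadence_days: int = 30
    days_supply: int = 30
    # Per-line probability of one >=90-day treatment interruption (same
    # drug resumed); short refill jitter below the gap threshold is applied
    # independently so the discontinuation boundary is exercised from both
    # sides.
    interruption_probability: float = 0.12
    jitter_probability: float = 0.20
    # Final-line end events.  For final lines at 3L or later the defaults
    # follow the observed 3L end-event mix conditional on no further line;
    # earlier final lines end by discontinuation or censoring only.
    p_hsct_final_3l: float = 0.0845
    p_apbc_final_3l: float = 0.080
    p_discontinue_final_3l: float = 0.113
    p_discontinue_final_early: float = 0.20
    # Treatment-free gap before the next line, carved out of the sampled
    # line duration (a switch ends the line at the next drug's first fill,
    # so the gap is part of the line).  Mostly short refill-like delays;
    # occasionally a long >=90-day gap, which is still a switch, not a
    # discontinuation.
    treatment_free_short_max_days: int = 15
    treatment_free_long_prob: float = 0.08
    treatment_free_long_range_days: tuple[int, int] = (90, 150)

    hru: HRURates = Field(default_factory=HRURates)
    costs: CostModel = Field(default_factory=CostModel)

    dx_year_range: tuple[int, int] = (2007, 2012)
    pre_dx_enrollment_min_days: int = 230
    pre_dx_enrollment_max_days: int = 600
    age_at_dx_mean: float = 55.0
    age_at_dx_sd: float = 13.0
    p_female: float = 0.497
    region_distribution: dict[str, float] = Field(
        default_factory=lambda: {
            "south": 0.405, "midwest": 0.274, "northeast": 0.149, "west": 0.172,
        }
    )
    comorbidity_prevalence: dict[str, float] = Field(
        default_factory=lambda: {
            "cardiac_arrhythmias": 0.186,
            "chronic_pulmonary_disease": 0.152,
            "congestive_heart_failure": 0.108,
            "diabetes": 0.250,
            "hypertension": 0.453,
            "valvular_disease": 0.118,
            "cirrhosis": 0.020,
            "end_stage_renal_disease": 0.015,
        }
    )
    darkow_class_distribution: dict[str, float] = Field(
        default_factory=lambda: {"mild": 0.358, "moderate": 0.351, "severe": 0.291}
    )
    code_attach_probability: float = 0.30
    p_hydroxyurea_pretreatment: float = 0.071
    p_other_drug_fills: float = 0.10
    # Selection-cascade exercise: small shares of patients engineered to
    # fail one criterion (enrollment gap, remission code, clinical-trial
    # code, late 1L start, HMO coverage for Medicare).
    p_enrollment_gap: float = 0.02
    p_remission_code: float = 0.02
    p_trial_code: float = 0.02
    p_late_1l: float = 0.02
    p_hmo: float = 0.0  # meaningful for medicare populations
    p_death: float = 0.0  # medicare: decedents (death after observation end)
    p_early_death: float = 0.0  # medicare: death < 12 months post-dx (waiver)

    @model_validator(mode="after")
    def _check(self) -> "TrajectorySpec":
        for name, dist in (
            ("line_count_distribution", self.line_count_distribution),
            ("first_line_drug_distribution", self.first_line_drug_distribution),
            ("region_distribution", self.region_distribution),
            ("darkow_class_distribution", self.darkow_class_distribution),
        ):
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"{name} sums to {total}, expected 1")
            if any(p < 0 for p in dist.values()):
                raise ConfigError(f"{name} has negative probability")
        if any(w < 0 for w in self.transition_weights.values()):
            raise ConfigError("transition weights must be non-negative")
        bad = set(self.first_line_drug_distribution) - set(FIRST_LINE_ELIGIBLE_DRUGS)
        if bad:
            raise ConfigError(f"first-line distribution includes ineligible drugs: {bad}")
        return self

    def transition_matrix(self) -> pd.DataFrame:
        """Realized switch matrix: rows renormalized with a zero diagonal."""
        drugs = list(CML_CP_DRUGS)
        rows = {}
        for cur in drugs:
            w = np.array(
                [0.0 if d == cur else self.transition_weights.get(d, 0.0) for d in drugs]
            )
            rows[cur] = w / w.sum()
        return pd.DataFrame(rows, index=drugs).T


@dataclass
class TrueLine:
    line_number: int
    drug: str
    start: dt.date
    end: dt.date
    supply_end: dt.date
    end_event: str
    n_fills: int
    interruption_count: int
    treatment_free_days_to_next: Optional[int] = None


@dataclass
class PatientTruth:
    patient_id: str
    payer: str
    dx_date: dt.date
    line1_start: dt.date
    observation_end: dt.date
    lines: list[TrueLine] = field(default_factory=list)
    follow_up: Optional[tuple[dt.date, dt.date]] = None
    period_person_days: dict[str, int] = field(default_factory=dict)
    period_costs: dict[str, dict[str, float]] = field(default_factory=dict)
    excluded_mode: Optional[str] = None


@dataclass
class GroundTruth:
    patients: dict[str, PatientTruth] = field(default_factory=dict)

    def lines_frame(self) -> pd.DataFrame:
        rows = []
        for pid in sorted(self.patients):
            t = self.patients[pid]
            for ln in t.lines:
                rows.append(
                    {
                        "patient_id": pid,
                        "line_number": ln.line_number,
                        "drug": ln.drug,
                        "start_date": ln.start,
                        "end_date": ln.end,
                        "supply_end_date": ln.supply_end,
                        "end_event": ln.end_event,
                        "n_fills": ln.n_fills,
                        "interruption_count": ln.interruption_count,
                        "treatment_free_days_to_next": ln.treatment_free_days_to_next,
                    }
                )
        return pd.DataFrame(rows)


def _sample_choice(rng: np.random.Generator, dist: dict) -> object:
    keys = sorted(dist, key=str)
    probs = np.array([dist[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    return keys[rng.choice(len(keys), p=probs)]


def _duration_days(rng: np.random.Generator, spec: TrajectorySpec, line_no: int) -> int:
    idx = min(line_no - 1, len(spec.line_duration_median_months) - 1)
    median = spec.line_duration_median_months[idx]
    sigma = spec.line_duration_sigma[min(idx, len(spec.line_duration_sigma) - 1)]
    months = float(rng.lognormal(mean=np.log(median), sigma=sigma))
    return max(1, int(round(months * 30.4375)))


def _fill_offsets(
    rng: np.random.Generator, spec: TrajectorySpec, duration_days: int, last: bool
) -> tuple[list[int], int]:
    """Fill-day offsets within a line and the number of true interruptions.

    Base cadence every ``fill_cadence_days``.  For a non-final line the
    schedule stops early enough to leave the sampled treatment-free gap
    before the next line starts at ``start + duration_days`` (occasionally
    a long >=90-day gap; the switch rule still applies).  An interruption
    removes a run of 3-5 consecutive fills, opening a gap of 90-150 days
    between the surrounding supply end and the resumption fill; refill
    jitter shifts a suffix of the schedule by a few days (gap < 90, no
    interruption).
    """
    c = spec.fill_cadence_days
    if last:
        n = max(1, int(round(duration_days / c)))
    else:
        if rng.random() < spec.treatment_free_long_prob:
            lo, hi = spec.treatment_free_long_range_days
            tf_target = int(rng.integers(lo, hi + 1))
        else:
            tf_target = int(rng.integers(0, spec.treatment_free_short_max_days + 1))
        n = max(1, (duration_days - tf_target) // c)
    offsets = [k * c for k in range(n)]
    interruptions = 0
    if n >= 5 and rng.random() < spec.interruption_probability:
        max_skip = min(5, n - 2)
        skip = int(rng.integers(3, max_skip + 1)) if max_skip >= 3 else 0
        if skip:
            at = int(rng.integers(1, n - skip))
            offsets = offsets[:at] + offsets[at + skip:]
            interruptions = 1
    if len(offsets) >= 2 and rng.random() < spec.jitter_probability:
        j = int(rng.integers(3, 25))
        b = int(rng.integers(1, len(offsets)))
        offsets = offsets[:b] + [o + j for o in offsets[b:]]
    return offsets, interruptions


def _eligible_drugs(
    candidates: dict[str, float],
    start: dt.date,
    config: StudyConfig,
    exclude: Optional[str] = None,
) -> dict[str, float]:
    ok = {
        d: w
        for d, w in candidates.items()
        if w > 0 and d != exclude and config.approval_dates[d].earliest <= start
    }
    if ok:
        return ok
    # Fallback: the earliest-approved drug other than the excluded one.
    for d in ("imatinib", "dasatinib", "nilotinib"):
        if d != exclude and config.approval_dates[d].earliest <= start:
            return {d: 1.0}
    return {"imatinib": 1.0}


def generate_cohort(
    spec: TrajectorySpec, config: Optional[StudyConfig] = None
) -> tuple[ClaimsBundle, GroundTruth]:
    """Generate a claims bundle and its ground truth, deterministically.

    The same spec (including its seed) always yields an identical bundle.
    """
    config = config or StudyConfig()
    rng = np.random.default_rng(spec.seed)
    medicare = spec.payer == "medicare"

    ph_rows: list[tuple] = []
    med_rows: list[tuple] = []
    enr_rows: list[tuple] = []
    pat_rows: list[tuple] = []
    truth = GroundTruth()

    cpi = config.cpi_table
    target = config.target_cost_year

    def deflate(amount: float, year: int) -> float:
        return amount * cpi[year] / cpi[target]

    def gamma(model: GammaCost) -> float:
        return float(rng.gamma(model.shape, model.scale))

    def add_pharmacy(pid, day: dt.date, drug: str, supply: int, amount_target: float):
        ph_rows.append(
            (pid, day, drug, supply, round(deflate(amount_target, day.year), 2), day.year)
        )

    def add_medical(pid, start: dt.date, end: dt.date, setting: str,
                    dx: list[str], procs: list[str], amount_target: float):
        med_rows.append(
            (
                pid, start, end, setting, ";".join(dx), ";".join(procs),
                round(deflate(amount_target, start.year), 2), start.year,
            )
        )

    cml_code = "C92.10"
    noncml_code = "R69"

    for i in range(spec.n_patients):
        pid = f"P{i:05d}"
        dx_year = int(rng.integers(spec.dx_year_range[0], spec.dx_year_range[1] + 1))
        dx_date = dt.date(dx_year, 1, 1) + int(rng.integers(0, 365)) * _DAY

        # Engineered exclusion mode, if any.
        mode = None
        r = rng.random()
        cum = 0.0
        for name, p in (
            ("enrollment_gap", spec.p_enrollment_gap),
            ("remission_code", spec.p_remission_code),
            ("trial_code", spec.p_trial_code),
            ("late_1l", spec.p_late_1l),
            ("hmo", spec.p_hmo if medicare else 0.0),
            ("early_death", spec.p_early_death if medicare else 0.0),
        ):
            cum += p
            if r < cum:
                mode = name
                break

        _, after = config.dx_to_1l_window(spec.payer)
        if mode == "late_1l":
            delay = after + int(rng.integers(30, 200))
        else:
            delay = int(rng.integers(0, min(after, 92)))
        line1_start = dx_date + delay * _DAY

        n_lines = int(_sample_choice(rng, spec.line_count_distribution))

        # --- true trajectory ------------------------------------------------
        planned: list[dict] = []
        cur_start = line1_start
        prev_drug: Optional[str] = None
        for k in range(1, n_lines + 1):
            if k == 1:
                cands = _eligible_drugs(
                    dict(spec.first_line_drug_distribution), cur_start, config
                )
            else:
                cands = _eligible_drugs(
                    dict(spec.transition_weights), cur_start, config, exclude=prev_drug
                )
            drug = str(_sample_choice(rng, cands))
            dur = _duration_days(rng, spec, k)
            offsets, interruptions = _fill_offsets(rng, spec, dur, last=(k == n_lines))
            fills = [cur_start + o * _DAY for o in offsets]
            supply_end = fills[-1] + spec.days_supply * _DAY
            entry = {
                "line_number": k,
                "drug": drug,
                "start": cur_start,
                "planned_end": cur_start + dur * _DAY,
                "fills": fills,
                "supply_end": supply_end,
                "interruptions": interruptions,
            }
            planned.append(entry)
            prev_drug = drug
            if k < n_lines:
                # The next line starts exactly at the sampled duration; the
                # treatment-free gap is whatever remains after the last
                # fill's supply (possibly zero).
                cur_start = entry["planned_end"]

        last = planned[-1]
        terminal: Optional[tuple[str, dt.date]] = None
        censor_intent = False
        if n_lines >= 3:
            r = rng.random()
            if r < spec.p_hsct_final_3l:
                terminal = ("hsct", last["supply_end"] + int(rng.integers(0, 61)) * _DAY)
            elif r < spec.p_hsct_final_3l + spec.p_apbc_final_3l:
                terminal = ("apbc", last["supply_end"] + int(rng.integers(0, 91)) * _DAY)
            elif r < spec.p_hsct_final_3l + spec.p_apbc_final_3l + spec.p_discontinue_final_3l:
                planned_obs = last["supply_end"] + (config.gap_days + int(rng.integers(0, 301))) * _DAY
            else:
                # Censored while on therapy: observation ends at the sampled
                # true duration, so realized durations track the duration
                # distribution (the residual gap is < gap_days).
                planned_obs = last["planned_end"]
                censor_intent = True
        else:
            if rng.random() < spec.p_discontinue_final_early:
                planned_obs = last["supply_end"] + (config.gap_days + int(rng.integers(0, 301))) * _DAY
            else:
                planned_obs = last["planned_end"]
                censor_intent = True
        if terminal is not None:
            planned_obs = terminal[1] + int(rng.integers(30, 366)) * _DAY
        # Plan enrollment runs at least through the 12-month post-diagnosis
        # requirement, as it must for any patient meant to enter the cohort.
        # A patient censored on therapy keeps refilling through that minimum
        # (still on the line when observation ends).
        min_obs = dx_date + (config.post_dx_enrollment_days + 30) * _DAY
        if planned_obs < min_obs:
            if censor_intent:
                while last["supply_end"] < min_obs:
                    last["fills"].append(last["supply_end"])
                    last["supply_end"] = last["fills"][-1] + spec.days_supply * _DAY
                last["planned_end"] = min_obs
            planned_obs = min_obs

        # --- enrollment -----------------------------------------------------
        enroll_start = dx_date - (
            config.washout_days
            + int(rng.integers(spec.pre_dx_enrollment_min_days - config.washout_days,
                               spec.pre_dx_enrollment_max_days - config.washout_days))
        ) * _DAY
        enroll_start = max(enroll_start, config.data_start)
        hmo = mode == "hmo"
        death_date: Optional[dt.date] = None
        spans: list[EnrollmentSpan] = []
        if mode == "enrollment_gap":
            if rng.random() < 0.5:
                # washout shortfall: coverage starts inside the washout window
                short_start = line1_start - int(
                    rng.integers(30, config.washout_days)
                ) * _DAY
                spans.append(EnrollmentSpan(pid, short_start, min(planned_obs, config.data_end)))
            else:
                # gap after diagnosis: two disjoint spans
                cut = dx_date + int(rng.integers(120, 300)) * _DAY
                gap = int(rng.integers(5, 40))
                spans.append(EnrollmentSpan(pid, enroll_start, cut))
                resume = cut + (gap + 1) * _DAY
                if resume <= min(planned_obs, config.data_end):
                    spans.append(
                        EnrollmentSpan(pid, resume, min(planned_obs, config.data_end))
                    )
        elif mode == "early_death":
            death_date = dx_date + int(rng.integers(100, 300)) * _DAY
            spans.append(EnrollmentSpan(pid, enroll_start, death_date, hmo_flag=hmo))
        else:
            spans.append(
                EnrollmentSpan(
                    pid, enroll_start, min(planned_obs, config.data_end), hmo_flag=hmo
                )
            )
        for s in spans:
            enr_rows.append((pid, s.start_date, s.end_date, "ppo", s.hmo_flag))

        merged = merge_enrollment(spans, config.enrollment_merge_gap_days)
        obs_span = span_containing(merged, line1_start)
        if obs_span is None:
            obs_end = line1_start  # degenerate; no observable therapy
        else:
            obs_end = min(obs_span.end_date, config.data_end)
        if death_date is not None:
            obs_end = min(obs_end, death_date)

        if medicare and mode is None and rng.random() < spec.p_death:
            death_date = obs_end + int(rng.integers(1, 366)) * _DAY

        # --- truncate trajectory at the observation end and derive truth ----
        if terminal is not None and terminal[1] > obs_end:
            terminal = None
        true_lines: list[TrueLine] = []
        for entry in planned:
            kept = [f for f in entry["fills"] if f <= obs_end]
            if not kept:
                break
            supply_end = kept[-1] + spec.days_supply * _DAY
            interruptions = sum(
                1
                for a, b in zip(kept, kept[1:])
                if (b - (a + spec.days_supply * _DAY)).days >= config.gap_days
            )
            line = TrueLine(
                line_number=entry["line_number"],
                drug=entry["drug"],
                start=entry["start"],
                end=entry["start"],  # provisional
                supply_end=supply_end,
                end_event="censored",  # provisional
                n_fills=len(kept),
                interruption_count=interruptions,
            )
            entry["kept"] = kept
            true_lines.append(line)
        for idx, line in enumerate(true_lines):
            is_last = idx == len(true_lines) - 1
            intact = line.n_fills == len(planned[idx]["fills"])
            if not is_last and intact:
                nxt = true_lines[idx + 1]
                line.end = nxt.start
                line.end_event = "switch"
                line.treatment_free_days_to_next = max(
                    0, (nxt.start - line.supply_end).days
                )
            else:
                if is_last and intact and terminal is not None:
                    line.end_event, line.end = (
                        ("hsct", terminal[1])
                        if terminal[0] == "hsct"
                        else ("apbc_chemo", terminal[1])
                    )
                elif (obs_end - line.supply_end).days >= config.gap_days:
                    line.end_event = "discontinuation"
                    line.end = line.supply_end
                else:
                    line.end_event = "censored"
                    line.end = obs_end
                true_lines = true_lines[: idx + 1]
                break

        # --- pharmacy claims ------------------------------------------------
        for entry in planned:
            for f in entry["fills"]:
                if f > obs_end:  # fills never postdate disenrollment/death
                    continue
                add_pharmacy(
                    pid, f, entry["drug"], spec.days_supply, gamma(spec.costs.pharmacy_fill)
                )
        if rng.random() < spec.p_hydroxyurea_pretreatment:
            n_hu = int(rng.integers(1, 4))
            lo = max((dx_date - 60 * _DAY), enroll_start)
            hi = max(lo, line1_start - _DAY)
            span_days = (hi - lo).days
            for _ in range(n_hu):
                d = lo + int(rng.integers(0, span_days + 1)) * _DAY
                add_pharmacy(pid, d, "hydroxyurea", 30, gamma(spec.costs.hydroxyurea_fill))
        if rng.random() < spec.p_other_drug_fills:
            for _ in range(int(rng.integers(1, 3))):
                d = enroll_start + int(
                    rng.integers(0, max(1, (obs_end - enroll_start).days + 1))
                ) * _DAY
                add_pharmacy(pid, d, "other", 30, gamma(spec.costs.other_fill))

        # --- terminal-event claims -------------------------------------------
        if terminal is not None and terminal[0] == "hsct":
            h = terminal[1]
            adm_start = h - int(rng.integers(0, 4)) * _DAY
            adm_end = min(h + int(rng.integers(7, 26)) * _DAY, obs_end)
            adm_days = (adm_end - adm_start).days + 1
            add_medical(
                pid, adm_start, adm_end, "inpatient", [cml_code], [],
                gamma(spec.costs.hsct_admission),
            )
            add_medical(
                pid, h, h, "inpatient", [cml_code],
                [config.codes.hsct_procedures[0]],
                gamma(spec.costs.ip_day) * max(1, adm_days // 2),
            )
        elif terminal is not None and terminal[0] == "apbc":
            a = terminal[1]
            add_medical(
                pid, a, a, "outpatient", [cml_code],
                [config.codes.ap_bc_chemo[0]], gamma(spec.costs.op_visit) * 3,
            )

        # --- diagnosis claim and exclusion-mode claims -----------------------
        dx_codes = [cml_code]
        if medicare:
            dx_codes.append(config.codes.cml_dx_medicare[0])
        add_medical(pid, dx_date, dx_date, "outpatient", dx_codes, [], gamma(spec.costs.op_visit))
        if mode == "remission_code":
            d = min(line1_start, dx_date + int(rng.integers(0, delay + 1)) * _DAY)
            add_medical(
                pid, d, d, "outpatient", [config.codes.cml_remission[0]], [],
                gamma(spec.costs.op_visit),
            )
        if mode == "trial_code":
            d = dx_date + int(rng.integers(0, 101)) * _DAY
            if d <= obs_end:
                add_medical(
                    pid, d, d, "outpatient",
                    [noncml_code, config.codes.clinical_trial[0]], [],
                    gamma(spec.costs.op_visit),
                )

        # --- background HRU claims -------------------------------------------
        window_days = max(1, (obs_end - enroll_start).days + 1)
        years = window_days / config.year_length_days
        present_conditions = [
            cond
            for cond in sorted(spec.comorbidity_prevalence)
            if rng.random() < spec.comorbidity_prevalence[cond]
        ]
        darkow_class = str(_sample_choice(rng, spec.darkow_class_distribution))

        def decorate(codes: list[str], day: dt.date) -> list[str]:
            for cond in present_conditions:
                if rng.random() < spec.code_attach_probability:
                    codes.append(config.comorbidity_map[cond][0])
            if darkow_class != "mild" and day >= dx_date:
                if rng.random() < spec.code_attach_probability:
                    codes.append(config.darkow_map[darkow_class][0])
            return codes

        # outpatient service days: distinct dates by construction
        n_op = int(rng.poisson(spec.hru.op_days * years))
        n_op = min(n_op, window_days)
        op_offsets = rng.choice(window_days, size=n_op, replace=False)
        for off in sorted(int(o) for o in op_offsets):
            day = enroll_start + off * _DAY
            if day == dx_date:
                continue
            cml = day >= dx_date and rng.random() < spec.hru.cml_frac_op
            codes = decorate([cml_code if cml else noncml_code], day)
            add_medical(pid, day, day, "outpatient", codes, [], gamma(spec.costs.op_visit))

        n_ed = int(rng.poisson(spec.hru.ed_visits * years))
        n_ed = min(n_ed, window_days)
        ed_offsets = rng.choice(window_days, size=n_ed, replace=False)
        for off in sorted(int(o) for o in ed_offsets):
            day = enroll_start + off * _DAY
            cml = day >= dx_date and rng.random() < spec.hru.cml_frac_ed
            add_medical(
                pid, day, day, "emergency",
                [cml_code if cml else noncml_code], [], gamma(spec.costs.ed_visit),
            )

        n_ip = int(rng.poisson(spec.hru.ip_admissions * years))
        for _ in range(n_ip):
            admit = enroll_start + int(rng.integers(0, window_days)) * _DAY
            los = 1 + int(rng.poisson(max(0.0, spec.hru.ip_los_mean - 1)))
            end = min(admit + (los - 1) * _DAY, obs_end)
            los = (end - admit).days + 1
            cml = admit >= dx_date and rng.random() < spec.hru.cml_frac_ip
            add_medical(
                pid, admit, end, "inpatient",
                [cml_code if cml else noncml_code], [],
                gamma(spec.costs.ip_day) * los,
            )

        # --- demographics ----------------------------------------------------
        age = int(np.clip(rng.normal(spec.age_at_dx_mean, spec.age_at_dx_sd), 18, 90))
        pat_rows.append(
            (
                pid,
                dx_year - age,
                "F" if rng.random() < spec.p_female else "M",
                str(_sample_choice(rng, spec.region_distribution)),
                death_date,
                spec.payer,
            )
        )

        pt = PatientTruth(
            patient_id=pid,
            payer=spec.payer,
            dx_date=dx_date,
            line1_start=line1_start,
            observation_end=obs_end,
            lines=true_lines,
            excluded_mode=mode,
        )
        if len(true_lines) >= 3:
            terminal_date = (
                true_lines[-1].end
                if true_lines[-1].end_event in ("hsct", "apbc_chemo")
                else None
            )
            index = true_lines[2].start
            fu_end = min(obs_end, terminal_date) if terminal_date else obs_end
            pt.follow_up = (index, fu_end)
            pt.period_person_days["3L+"] = (fu_end - index).days
            w3_end = min(true_lines[2].end, fu_end)
            pt.period_person_days["3L"] = max(0, (w3_end - index).days)
            if len(true_lines) >= 4:
                w4_start = true_lines[3].start
                w4_end = min(true_lines[3].end, fu_end)
                pt.period_person_days["4L"] = max(0, (w4_end - w4_start).days)
        truth.patients[pid] = pt

    bundle = ClaimsBundle(
        pharmacy=pd.DataFrame(ph_rows, columns=PHARMACY_COLUMNS),
        medical=pd.DataFrame(med_rows, columns=MEDICAL_COLUMNS),
        enrollment=pd.DataFrame(enr_rows, columns=ENROLLMENT_COLUMNS),
        patients=pd.DataFrame(pat_rows, columns=PATIENT_COLUMNS),
    ).sort()
    _attach_truth_costs(bundle, truth, config)
    return bundle, truth


def _attach_truth_costs(
    bundle: ClaimsBundle, truth: GroundTruth, config: StudyConfig
) -> None:
    """Brute-force all-cause per-period component costs for 3L+ patients.

    Deliberately naive (day-by-day enumeration for inpatient pro-ration) so
    it can serve as an independent oracle for the cost pipeline.
    """
    cpi = config.cpi_table
    target = config.target_cost_year
    ph_groups = dict(tuple(bundle.pharmacy.groupby("patient_id", sort=True)))
    med_groups = dict(tuple(bundle.medical.groupby("patient_id", sort=True)))
    for pid, pt in truth.patients.items():
        if pt.follow_up is None:
            continue
        windows: dict[str, tuple[dt.date, dt.date]] = {"3L+": pt.follow_up}
        fu_start, fu_end = pt.follow_up
        l3 = pt.lines[2]
        windows["3L"] = (l3.start, min(l3.end, fu_end))
        if len(pt.lines) >= 4:
            l4 = pt.lines[3]
            windows["4L"] = (l4.start, min(l4.end, fu_end))
        for label, (start, end) in windows.items():
            comp = {"pharmacy": 0.0, "ip": 0.0, "op": 0.0, "ed": 0.0}
            ph = ph_groups.get(pid)
            if ph is not None:
                for row in ph.itertuples():
                    if start <= row.fill_date < end:
                        comp["pharmacy"] += row.paid_amount * cpi[target] / cpi[row.service_year]
            med = med_groups.get(pid)
            if med is not None:
                for row in med.itertuples():
                    paid = row.paid_amount * cpi[target] / cpi[row.service_year]
                    if row.setting == "inpatient":
                        total_days = (row.end_date - row.start_date).days + 1
                        day = row.start_date
                        while day <= row.end_date:
                            if start <= day < end:
                                comp["ip"] += paid / total_days
                            day += _DAY
                    elif row.setting == "outpatient":
                        if start <= row.start_date < end:
                            comp["op"] += paid
                    elif row.setting == "emergency":
                        if start <= row.start_date < end:
                            comp["ed"] += paid
            comp["total"] = sum(comp.values())
            pt.period_costs[label] = comp


class NoiseSpec(BaseModel):
    """Claims that must not alter constructed lines."""

    n_other_fills: int = 2
    n_noncml_op: int = 3
    n_hydroxyurea_fills: int = 1
    seed: int = 1


def inject_noise(
    bundle: ClaimsBundle, spec: NoiseSpec, config: Optional[StudyConfig] = None
) -> ClaimsBundle:
    """Add non-line-defining noise: ``other`` fills, non-CML outpatient
    claims, and hydroxyurea fills inside each patient's enrollment."""
    config = config or StudyConfig()
    rng = np.random.default_rng(spec.seed)
    ph_rows = []
    med_rows = []
    for row in bundle.enrollment.itertuples():
        pid = row.patient_id
        span_days = (row.end_date - row.start_date).days + 1

        def rand_day() -> dt.date:
            return row.start_date + int(rng.integers(0, span_days)) * _DAY

        for _ in range(spec.n_other_fills):
            d = rand_day()
            ph_rows.append((pid, d, "other", 30, 50.0, d.year))
        for _ in range(spec.n_hydroxyurea_fills):
            d = rand_day()
            ph_rows.append((pid, d, "hydroxyurea", 30, 40.0, d.year))
        for _ in range(spec.n_noncml_op):
            d = rand_day()
            med_rows.append((pid, d, d, "outpatient", "R69", "", 120.0, d.year))
    out = ClaimsBundle(
        pharmacy=pd.concat(
            [bundle.pharmacy, pd.DataFrame(ph_rows, columns=PHARMACY_COLUMNS)],
            ignore_index=True,
        ),
        medical=pd.concat(
            [bundle.medical, pd.DataFrame(med_rows, columns=MEDICAL_COLUMNS)],
            ignore_index=True,
        ),
        enrollment=bundle.enrollment.copy(),
        patients=bundle.patients.copy(),
    )
    return out.sort()
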