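"""Selection cascade: single-criterion probes, brute-force oracle, follow-up."""

from __future__ import annotations

import datetime as dt
import random

import pandas as pd
import pytest

from cmlclaims.cohort import (
    CRITERIA_LABELS,
    apply_selection,
    check_washout,
    define_follow_up,
    first_cml_diagnosis,
)
from cmlclaims.config import FIRST_LINE_ELIGIBLE_DRUGS, StudyConfig, any_code_matches
from cmlclaims.lines import build_lines, collect_therapy_events
from cmlclaims.model import (
    ClaimsBundle,
    EnrollmentSpan,
    MedicalClaim,
    PatientRecord,
    PharmacyClaim,
    covers,
    merge_enrollment,
    span_containing,
    split_codes,
)

D = dt.date


def op_claim(pid, date, codes=("C92.10",), procs=()):
    return MedicalClaim(pid, date, date, "outpatient", tuple(codes), tuple(procs), 100.0, date.year)


def make_patient(
    pid,
    payer="commercial",
    birth_year=1960,
    dx=D(2010, 1, 10),
    dx_codes=("C92.10",),
    enroll=(D(2009, 1, 1), D(2016, 12, 31)),
    hmo=False,
    death=None,
    line_starts=((D(2010, 2, 1), "imatinib"), (D(2010, 6, 1), "dasatinib"), (D(2010, 10, 1), "nilotinib")),
    extra_pharmacy=(),
    extra_medical=(),
):
    """A patient who passes every criterion unless perturbed."""
    pharmacy = list(extra_pharmacy)
    for start, drug in line_starts:
        for k in range(3):
            d = start + dt.timedelta(days=30 * k)
            pharmacy.append(PharmacyClaim(pid, d, drug, 30, 9000.0, d.year))
    medical = [op_claim(pid, dx, dx_codes)] + list(extra_medical)
    enrollment = [EnrollmentSpan(pid, enroll[0], enroll[1], hmo_flag=hmo)]
    patient = PatientRecord(pid, birth_year, "F", "south", death, payer)
    return pharmacy, medical, enrollment, [patient]


def bundle_of(*patients) -> ClaimsBundle:
    ph, med, enr, pat = [], [], [], []
    for p in patients:
        ph += p[0]
        med += p[1]
        enr += p[2]
        pat += p[3]
    return ClaimsBundle.from_records(ph, med, enr, pat)


def excluded_at(bundle, config, pid):
    result = apply_selection(bundle, config)
    return result.patients[pid].excluded_at


class TestFirstCmlDiagnosis:
    def test_earliest_cml_coded_claim(self, config):
        b = bundle_of(make_patient("p"))
        med = ClaimsBundle.from_records(
            medical=[op_claim("p", D(2010, 3, 1)), op_claim("p", D(2010, 1, 15))]
        ).medical
        assert first_cml_diagnosis(med, config.codes.cml_dx) == D(2010, 1, 15)

    def test_absent_without_cml_codes(self, config):
        med = ClaimsBundle.from_records(
            medical=[op_claim("p", D(2010, 3, 1), codes=("R69",))]
        ).medical
        assert first_cml_diagnosis(med, config.codes.cml_dx) is None

    def test_matches_linear_scan_oracle(self, config):
        rng = random.Random(4)
        claims = []
        base = D(2008, 1, 1)
        for _ in range(200):
            d = base + dt.timedelta(days=rng.randint(0, 2000))
            code = rng.choice(["C92.10", "205.12", "R69", "I10", "C92.1"])
            claims.append(op_claim("p", d, codes=(code,)))
        med = ClaimsBundle.from_records(medical=claims).medical
        expected = min(
            (c.start_date for c in claims
             if any_code_matches(c.diagnosis_codes, config.codes.cml_dx)),
            default=None,
        )
        assert first_cml_diagnosis(med, config.codes.cml_dx) == expected


class TestWashout:
    def _frames(self, pharmacy, enroll_start=D(2009, 1, 1)):
        b = ClaimsBundle.from_records(pharmacy=pharmacy)
        spans = merge_enrollment([EnrollmentSpan("p", enroll_start, D(2015, 1, 1))], 0)
        return b.pharmacy, b.medical, spans

    def test_tki_fill_inside_window_violates(self, config):
        l1 = D(2010, 6, 1)
        ph, med, spans = self._frames(
            [PharmacyClaim("p", l1 - dt.timedelta(days=100), "imatinib", 30, 1.0, 2010)]
        )
        assert not check_washout(ph, med, l1, 183, spans, config)

    def test_clean_window_with_coverage_passes(self, config):
        l1 = D(2010, 6, 1)
        ph, med, spans = self._frames([])
        assert check_washout(ph, med, l1, 183, spans, config)

    def test_hydroxyurea_is_pretreatment_not_violation(self, config):
        l1 = D(2010, 6, 1)
        ph, med, spans = self._frames(
            [PharmacyClaim("p", l1 - dt.timedelta(days=100), "hydroxyurea", 30, 1.0, 2010)]
        )
        assert check_washout(ph, med, l1, 183, spans, config)

    def test_enrollment_shortfall_violates(self, config):
        l1 = D(2010, 6, 1)
        ph, med, spans = self._frames([], enroll_start=D(2010, 3, 1))
        assert not check_washout(ph, med, l1, 183, spans, config)


class TestSelectionProbes:
    """Each probe perturbs an otherwise-passing patient to fail one step."""

    def test_reference_patient_reaches_cohort(self, config):
        b = bundle_of(make_patient("ok"))
        result = apply_selection(b, config)
        assert result.cohort_ids == ["ok"]
        assert result.patients["ok"].index_date == D(2010, 10, 1)

    def test_no_cml_diagnosis(self, config):
        b = bundle_of(make_patient("p", dx_codes=("R69",)))
        assert excluded_at(b, config, "p") == CRITERIA_LABELS[0]

    def test_underage_at_1l(self, config):
        b = bundle_of(make_patient("p", birth_year=1995))
        assert excluded_at(b, config, "p") == CRITERIA_LABELS[1]

    def test_ineligible_1l_drug(self, config):
        # omacetaxine is a CML-CP drug but never an eligible first line
        b = bundle_of(
            make_patient(
                "p",
                dx=D(2013, 1, 10),
                line_starts=(
                    (D(2013, 2, 1), "omacetaxine"),
                    (D(2013, 6, 1), "dasatinib"),
                    (D(2013, 10, 1), "nilotinib"),
                ),
            )
        )
        assert excluded_at(b, config, "p") == CRITERIA_LABELS[2]

    def test_1l_outside_diagnosis_window(self, config):
        b = bundle_of(
            make_patient(
                "p",
                line_starts=(
                    (D(2010, 6, 1), "imatinib"),  # dx + 142 days > 91
                    (D(2010, 10, 1), "dasatinib"),
                    (D(2011, 2, 1), "nilotinib"),
                ),
            )
        )
        assert excluded_at(b, config, "p") == CRITERIA_LABELS[3]

    def test_washout_enrollment_shortfall(self, config):
        b = bundle_of(make_patient("p", enroll=(D(2010, 1, 1), D(2016, 12, 31))))
        assert excluded_at(b, config, "p") == CRITERIA_LABELS[4]

    def test_washout_pre_approval_therapy_claim(self, config):
        # a dasatinib fill 8 days before its FDA approval cannot define a
        # line but is still prior CML-CP therapy in the washout window
        dx = D(2006, 9, 10)
        b = bundle_of(
            make_patient(
                "p",
                dx=dx,
                enroll=(D(2005, 6, 1), D(2012, 12, 31)),
                line_starts=(
                    (D(2006, 10, 1), "imatinib"),
                    (D(2007, 2, 1), "dasatinib"),
                    (D(2007, 12, 1), "nilotinib"),
                ),
                extra_pharmacy=(
                    PharmacyClaim("p", D(2006, 6, 20), "dasatinib", 30, 1.0, 2006),
                ),
            )
        )
        assert excluded_at(b, config, "p") == CRITERIA_LABELS[4]

    def test_enrollment_gap_after_diagnosis(self, config):
        p = make_patient("p")
        # replace enrollment with two spans leaving a post-dx gap
        p = (
            p[0],
            p[1],
            [
                EnrollmentSpan("p", D(2009, 1, 1), D(2010, 8, 1)),
                EnrollmentSpan("p", D(2010, 9, 1), D(2016, 12, 31)),
            ],
            p[3],
        )
        assert excluded_at(bundle_of(p), config, "p") == CRITERIA_LABELS[5]

    def test_medicare_hmo_coverage_excluded(self, config):
        b = bundle_of(
            make_patient("p", payer="medicare", dx_codes=("9863",), hmo=True)
        )
        assert excluded_at(b, config, "p") == CRITERIA_LABELS[6]

    def test_commercial_hmo_flag_not_applied(self, config):
        b = bundle_of(make_patient("p", hmo=True))
        assert apply_selection(b, config).cohort_ids == ["p"]

    def test_medicare_death_waives_post_dx_enrollment(self, config):
        # enrollment and life end 8 months after diagnosis: the 12-month
        # requirement is waived, and the patient falls out only at 3L
        death = D(2010, 9, 10)
        b = bundle_of(
            make_patient(
                "p",
                payer="medicare",
                dx_codes=("9863",),
                enroll=(D(2009, 1, 1), death),
                death=death,
                line_starts=((D(2010, 2, 1), "imatinib"),),
            )
        )
        assert excluded_at(b, config, "p") == CRITERIA_LABELS[9]

    def test_commercial_death_does_not_waive(self, config):
        death = D(2010, 9, 10)
        b = bundle_of(
            make_patient(
                "p",
                enroll=(D(2009, 1, 1), death),
                death=death,
                line_starts=((D(2010, 2, 1), "imatinib"),),
            )
        )
        assert excluded_at(b, config, "p") == CRITERIA_LABELS[5]

    def test_remission_code_before_1l(self, config):
        b = bundle_of(
            make_patient(
                "p", extra_medical=(op_claim("p", D(2010, 1, 20), ("C92.11",)),)
            )
        )
        assert excluded_at(b, config, "p") == CRITERIA_LABELS[7]

    def test_relapse_code_before_1l(self, config):
        b = bundle_of(
            make_patient(
                "p", extra_medical=(op_claim("p", D(2010, 1, 20), ("205.12",)),)
            )
        )
        assert excluded_at(b, config, "p") == CRITERIA_LABELS[7]

    def test_remission_code_after_1l_is_ignored(self, config):
        b = bundle_of(
            make_patient(
                "p", extra_medical=(op_claim("p", D(2010, 3, 20), ("C92.11",)),)
            )
        )
        assert apply_selection(b, config).cohort_ids == ["p"]

    def test_clinical_trial_claim_before_index(self, config):
        b = bundle_of(
            make_patient(
                "p", extra_medical=(op_claim("p", D(2010, 3, 1), ("V70.7",)),)
            )
        )
        assert excluded_at(b, config, "p") == CRITERIA_LABELS[8]

    def test_never_reached_3l(self, config):
        b = bundle_of(
            make_patient(
                "p",
                line_starts=((D(2010, 2, 1), "imatinib"), (D(2010, 6, 1), "dasatinib")),
            )
        )
        assert excluded_at(b, config, "p") == CRITERIA_LABELS[9]


def _independent_criteria(bundle: ClaimsBundle, config: StudyConfig) -> dict[str, set]:
    """Each criterion evaluated independently for every patient (oracle)."""
    sets: dict[str, set] = {label: set() for label in CRITERIA_LABELS}
    ph_all = bundle.pharmacy
    med_all = bundle.medical
    for prow in bundle.patients.itertuples():
        pid = prow.patient_id
        ph = ph_all[ph_all["patient_id"] == pid]
        med = med_all[med_all["patient_id"] == pid]
        spans = [
            EnrollmentSpan(pid, r.start_date, r.end_date, r.plan_type, bool(r.hmo_flag))
            for r in bundle.enrollment[bundle.enrollment["patient_id"] == pid].itertuples()
        ]
        merged = merge_enrollment(spans, config.enrollment_merge_gap_days)
        dx = first_cml_diagnosis(med, config.cml_dx_codes(prow.payer))
        events = collect_therapy_events((ph, med), config)
        lines = []
        if events:
            span = span_containing(merged, events[0].date)
            if span is not None:
                obs = min(span.end_date, config.data_end)
                if prow.death_date is not None:
                    obs = min(obs, prow.death_date)
                lines = build_lines(events, obs, config.gap_days)
        l1 = lines[0].start_date if lines else None
        index = lines[2].start_date if len(lines) >= 3 else None

        if dx is not None:
            sets[CRITERIA_LABELS[0]].add(pid)
        if l1 is not None and l1.year - prow.birth_year >= 18:
            sets[CRITERIA_LABELS[1]].add(pid)
        if lines and lines[0].drug in FIRST_LINE_ELIGIBLE_DRUGS:
            sets[CRITERIA_LABELS[2]].add(pid)
        if dx is not None and l1 is not None:
            before, after = config.dx_to_1l_window(prow.payer)
            if dx - dt.timedelta(before) <= l1 <= dx + dt.timedelta(after):
                sets[CRITERIA_LABELS[3]].add(pid)
        if l1 is not None and check_washout(ph, med, l1, config.washout_days, merged, config):
            sets[CRITERIA_LABELS[4]].add(pid)
        if dx is not None and l1 is not None:
            w_start = l1 - dt.timedelta(config.washout_days)
            post = dx + dt.timedelta(config.post_dx_enrollment_days)
            waived = (
                prow.payer == "medicare"
                and prow.death_date is not None
                and prow.death_date <= post
            )
            end = min(post, prow.death_date) if waived else post
            if covers(merged, w_start, end):
                sets[CRITERIA_LABELS[5]].add(pid)
            hmo = prow.payer == "medicare" and any(
                s.hmo_flag and s.start_date <= end and s.end_date >= w_start
                for s in spans
            )
            if not hmo:
                sets[CRITERIA_LABELS[6]].add(pid)
        rem = config.codes.cml_remission + config.codes.cml_relapse
        if l1 is not None and not any(
            r.start_date <= l1 and any_code_matches(split_codes(r.diagnosis_codes), rem)
            for r in med.itertuples()
        ):
            sets[CRITERIA_LABELS[7]].add(pid)
        trial_hit = index is not None and any(
            r.start_date <= index
            and any_code_matches(split_codes(r.diagnosis_codes), config.codes.clinical_trial)
            for r in med.itertuples()
        )
        if not trial_hit:
            sets[CRITERIA_LABELS[8]].add(pid)
        if index is not None:
            sets[CRITERIA_LABELS[9]].add(pid)
    return sets


class TestCascadeProperties:
    def test_cascade_equals_intersection_of_independent_filters(
        self, small_population, config
    ):
        bundle, _ = small_population
        result = apply_selection(bundle, config)
        sets = _independent_criteria(bundle, config)
        expected = set(bundle.patients["patient_id"])
        for label in CRITERIA_LABELS:
            expected &= sets[label]
        assert set(result.cohort_ids) == expected

    def test_attrition_monotone_and_sums_to_input(self, small_population, config):
        bundle, _ = small_population
        result = apply_selection(bundle, config)
        frame = result.attrition.to_frame()
        remaining = frame["n_remaining"].tolist()
        assert all(a >= b for a, b in zip(remaining, remaining[1:]))
        assert frame["n_excluded"].sum() + len(result.cohort_ids) == remaining[0]
        assert remaining[0] == len(bundle.patients)
        assert remaining[-1] == len(result.cohort_ids)

    def test_row_order_never_changes_selection(self, small_population, config):
        bundle, _ = small_population
        base = apply_selection(bundle, config)
        shuffled = ClaimsBundle(
            pharmacy=bundle.pharmacy.sample(frac=1, random_state=1),
            medical=bundle.medical.sample(frac=1, random_state=2),
            enrollment=bundle.enrollment.sample(frac=1, random_state=3),
            patients=bundle.patients.sample(frac=1, random_state=4),
        )
        again = apply_selection(shuffled, config)
        assert again.cohort_ids == base.cohort_ids
        assert again.attrition.rows == base.attrition.rows

    def test_cohort_members_have_3_lines_and_index_is_3l_start(
        self, cohort_3l
    ):
        _, _, selection = cohort_3l
        for pid in selection.cohort_ids:
            sel = selection.patients[pid]
            assert len(sel.lines) >= 3
            assert sel.index_date == sel.lines[2].start_date
            assert sel.baseline_end == sel.index_date - dt.timedelta(days=1)
            assert sel.follow_up_start == sel.index_date
            assert sel.follow_up_end >= sel.index_date
            # no line exists after a terminal event
            for ln in sel.lines[:-1]:
                assert ln.end_event == "switch"


class TestFollowUp:
    def test_ends_at_enrollment_without_terminal_events(self):
        start, end = define_follow_up(D(2012, 1, 1), D(2013, 6, 1), D(2019, 6, 30))
        assert (start, end) == (D(2012, 1, 1), D(2013, 6, 1))

    def test_hsct_truncates_follow_up(self):
        start, end = define_follow_up(
            D(2012, 1, 1), D(2015, 1, 1), D(2019, 6, 30),
            hsct_date=D(2012, 4, 10),
        )
        assert (end - start).days == 100

    def test_matches_explicit_min_oracle(self):
        rng = random.Random(11)
        base = D(2012, 1, 1)
        for _ in range(200):
            index = base + dt.timedelta(rng.randint(0, 400))
            cands = {
                "enroll": index + dt.timedelta(rng.randint(0, 900)),
                "data": index + dt.timedelta(rng.randint(0, 900)),
                "hsct": index + dt.timedelta(rng.randint(0, 900)) if rng.random() < 0.5 else None,
                "apbc": index + dt.timedelta(rng.randint(0, 900)) if rng.random() < 0.5 else None,
            }
            _, end = define_follow_up(
                index, cands["enroll"], cands["data"], cands["hsct"], cands["apbc"]
            )
            assert end == min(v for v in cands.values() if v is not None)

    def test_zero_length_window_allowed_but_negative_is_defect(self):
        assert define_follow_up(D(2012, 1, 1), D(2012, 1, 1), D(2019, 1, 1)) == (
            D(2012, 1, 1), D(2012, 1, 1),
        )
        with pytest.raises(ValueError):
            define_follow_up(D(2012, 1, 1), D(2011, 12, 31), D(2019, 1, 1))
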