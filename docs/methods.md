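# Methods

This note documents the analysis model implemented by `cmlclaims`, the
conventions and defaults it uses, what the synthetic-data generator does and
does not emulate, and the design choices made where the methodology was
genuinely open.

## Data model and day conventions

All dates are whole calendar days; there are no timezones. Intervals in the
*data* are closed: an inpatient stay from admission `s` to discharge `e`
covers `e − s + 1` days. Gaps *between* events span `end − start` days.
Month-denominated windows use fixed day counts: 1 month = 30 days,
3 months = 91 days, 6 months = 183 days, 1 year = 365 days. The PPPM month
is 365.25 / 12 = 30.4375 days and a person-year is 365.25 days. These
conventions make every result reproducible to the day.

Diagnosis and procedure codes match by case-insensitive *prefix*, mirroring
the "205.1x" notation of claims studies. All code lists, thresholds,
approval dates and the CPI table live in `StudyConfig` and are overridable;
the shipped medical-care CPI values are annual index levels of the usual
published series (only ratios matter) and should be replaced with the exact
series for production use.

## Lines of therapy

Line-defining drugs are the six CML-CP therapies (imatinib, dasatinib,
nilotinib, bosutinib, ponatinib, omacetaxine). Fills before a drug's
earliest FDA approval date never define a line (they still count as prior
therapy in the washout). Omacetaxine may also enter through a
procedure-coded medical claim (one day of supply — an injectable).
Hydroxyurea and unrecognized drugs are never line-defining.

A line starts at the first claim for its drug; its supply end is
`fill_date + days_supply`, extended by each same-drug fill (taking the
maximum when fills overlap). The line ends at the earliest of:

1. **switch** — first fill of a different CML-CP drug, at that fill's date
   (the next line starts the same day). This holds even when the
   intervening gap exceeds 90 days: the observed treatment-free periods
   have heavy tails, and a different-drug fill signals a clinical decision,
   not an end of care.
2. **apbc_chemo** — a chemotherapy not listed for CML-CP (progression to
   accelerated phase / blast crisis). No later lines are constructed.
3. **hsct** — a stem-cell-transplant procedure. No later lines.
4. **discontinuation** — no further therapy of any kind and
   `observation_end − supply_end ≥ 90` days; the line ends at the supply
   end.
5. **censored** — otherwise, at the observation end.

A gap of ≥90 days from the supply end to a *same-drug* fill increments the
line's interruption count and does not end the line.

Deterministic tie-breaks for same-day events: HSCT > AP/BC chemotherapy >
switch. When two different CML-CP drugs are first filled on the same day,
the larger days-supply defines the line, alphabetical order breaking exact
ties. A same-drug fill on the very day of a switch is counted as a fill of
the ending line but never as an interruption (no resumption occurs).
Terminal events dated before the first therapy fill are ignored for line
construction; lines begin at the first fill by definition. Duration is
`(end − start) / 30.4375` months; censored lines contribute their censored
duration to the summary statistics (no survival adjustment), matching the
descriptive design. Duration buckets use closed upper bounds ("≤3",
">3 to ≤6"), with ">6" and ">12" cumulative (">12" ⊂ ">6").

## Cohort selection

The cascade order is fixed as listed in the README. Notes on the less
obvious steps:

* Patients with no constructed first line at all fall out at the "adult at
  1L" step (there is no 1L to be adult at).
* Because pre-approval fills are dropped at event collection, the "approved
  1L drug" step reduces to membership in {imatinib, dasatinib, nilotinib,
  bosutinib}; a patient whose only early fills predate approval instead
  shows prior therapy in the washout and is excluded there.
* The remission/relapse exclusion (205.11/C92.11, 205.12/C92.12) is
  anchored at or before 1L start; the clinical-trial exclusion
  (V70.7/Z00.6) at or before the index date. Patients who never reach 3L
  have no index date, so the trial criterion is vacuously satisfied and
  they fall out at the final step. Both windows are configurable.
* The Medicare death waiver applies only to the 12-month post-diagnosis
  enrollment requirement, and coverage is then required through death.
* Observation ends at the earliest of: end of the merged enrollment span
  containing the first therapy event, end of data availability, and death.
  Follow-up runs from the index date to the earliest of data end,
  enrollment end, HSCT and AP/BC chemotherapy.

## Outcomes

Analysis windows (3L+, 3L, 4L) are half-open day intervals `[start, end)`
clipped to follow-up; person-days = `end − start`. Annual incidence rates
are cohort-aggregate — total events over total person-days, × 365.25 — not
means of per-patient rates; with no person-time a rate is reported absent,
not zero. Overlapping or abutting inpatient claims are merged into single
admissions before counting; inpatient days are stay days clipped to the
window; outpatient days and ED visits are distinct service dates. A claim
is CML-related when any diagnosis position carries a CML code or a
procedure position carries an omacetaxine code; CML-related pharmacy is
restricted to the five TKIs (an omacetaxine fill is all-cause only).

Costs are plan-paid amounts (payer perspective; no out-of-pocket),
inflated multiplicatively with one CPI factor per calendar year (no
monthly interpolation), and reported PPPM: per-patient total divided by
person-months, summarized as mean/SD/median over patients with positive
person-time. Pharmacy fills attribute wholly to the fill date; inpatient
paid amounts are pro-rated linearly by the fraction of stay days inside the
window (avoids double counting across the 3L/4L boundary; whole-amount-at-
admission attribution is available via `ip_cost_attribution: start`).
Components sum to the total by construction. An HSCT event is costed as
the sum of inflated inpatient claims within the merged admission containing
the procedure date; a procedure with no containing admission is costed from
the procedure claim alone and flagged. The sensitivity analysis removes
exactly those admission claims and recomputes every summary.

## Small-cell suppression and formatting

Percentages round half-up to one decimal. With suppression enabled
(threshold 11 by default, the CMS policy for Medicare-derived output),
counts in [1, 10] are masked; when a group's total is public and exactly
one cell is masked, the smallest remaining displayable cell (zero included)
is masked too, so subtraction leaves an ambiguous split. A single-cell
group with a public total cannot be protected by masking — callers must
hide such totals. Suppression is off by default (it is data-source
specific) and enabled with `--suppress`.

## The synthetic-data generator

The generator emulates the *structure* that the line-construction and
outcome logic depends on, with defaults set to the study conditions for the
commercially insured population:

* line counts per 1L initiator: 70.5% / 20.3% / 6.6% / 1.8% / 0.4% / 0.3%
  for 1–6 lines (≈9.2% reaching 3L);
* lognormal true line durations with medians 8.47 / 4.24 / 8.32 / 8.39
  months for 1L–4L (dispersions matched to the reported mean/median
  ratios); 1L drug shares 64.9 / 21.6 / 13.5% for
  imatinib/dasatinib/nilotinib; switch targets drawn from preference
  weights with the current drug excluded (zero-diagonal transition matrix);
* 30-day fill cadence and supply; per-line probability 0.12 of one ≥90-day
  interruption (a skipped run of 3–5 fills) and 0.20 of a small (<90-day)
  refill-jitter shift, so the discontinuation boundary is exercised from
  both sides;
* final-line end events for lines ≥3: HSCT 8.45%, AP/BC chemotherapy
  8.0%, discontinuation 11.3%, otherwise censored on therapy — the
  observed third-line end-event mix conditional on no further line;
* background annual utilization: 0.4 inpatient admissions with mean stay
  8.5 days (hence 3.4 inpatient days), 30.8 outpatient-service days
  (sampled as distinct dates), 1.2 ED visits per person-year, with
  CML-related shares 83.1% / 75% / 50%; gamma paid amounts per component,
  drawn at target-year level and deflated to service-year dollars so that
  inflation recovers the configured means exactly.

Scheduling is duration-anchored: a switch line's next line starts exactly at
`start + duration`, with the treatment-free gap carved out of the sampled
duration (occasionally ≥90 days — still a switch), and a censored final
line's observation ends exactly at `start + duration`, so pipeline-estimated
duration medians recover the configured medians without systematic
inflation. Enrollment is planned to run at least through 12 months plus one
month after diagnosis (as it must for any patient meant to enter the
cohort); a patient censored on therapy keeps refilling through that
minimum. When a planned trajectory overruns the data window or an
engineered enrollment gap, the generator re-derives the final true line's
end event from its own fill structure with the same ≥90-day rule — boundary
arithmetic on known structure, not a re-run of the claim-stream builder.
Small shares of patients are engineered to fail individual selection
criteria (enrollment gaps, remission codes, trial codes, late 1L starts,
HMO coverage for Medicare). Washout violations are modelled through
enrollment shortfall rather than injected pre-1L TKI fills, because such
fills would themselves become line-defining events and change the true
lines.

What the generator does **not** emulate: real dictionary layouts (MarketScan
or Medicare), realistic code dictionaries beyond the configured prefix
lists, actuarially calibrated cost levels, dose/titration or adherence
behaviour, combination therapy, and calendar-time trends in drug choice
beyond FDA-approval gating. Passing tests therefore demonstrate the
correctness of the algorithms under the stated structural assumptions, not
the clinical realism of any particular number.

## Verification strategy and problem sizes

The test suite checks every operation against an independent oracle where
one exists: a deliberately naive single-pass reference implementation and
randomized event streams for the line builder (plus exact ground-truth
agreement on 1,000 simulated patients spanning every end-event mechanism);
per-criterion brute-force filters intersected for the selection cascade;
day-enumeration recounts for HRU; direct-ratio and brute-force
categorization for costs, with conservation identities (component
additivity at 1e-6 relative, CML-related ≤ all-cause everywhere,
main-minus-sensitivity equal to in-period HSCT claims) verified patient by
patient. Parameter recovery uses 2,000 patients for duration medians
(within 10%, with a 2007–2008 diagnosis window so the data end rarely
truncates) and ~1,600 person-years for rate recovery (within 3 standard
errors; terminal events disabled there because transplant and progression
claims are utilization *on top of* the background rates). Rounding and
suppression behaviour is fuzzed. These sizes keep the full suite under a
minute or two on a single CPU while leaving the statistical checks
well-powered.

## Known limitations

* Lines are monotherapy by construction; simultaneous multi-drug regimens
  are resolved by the deterministic same-day rule rather than modelled.
* A discontinuation can only be the last observed event of a patient's
  sequence; sequencing stops only at HSCT/AP-BC. A later different-drug
  fill after a long gap is a switch by design.
* Age is computed from birth year only (claims granularity); the modified
  Charlson map ships with the original 17-condition weights minus the CML
  codes and is fully configurable, as is the disease-complexity
  (mild/moderate/severe) code map, whose published lists are not
  replicated.
* The cohort-aggregate incidence-rate definition (total events over total
  person-time) was chosen over per-patient annualization; both are common,
  and the choice matters only under informative censoring.
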