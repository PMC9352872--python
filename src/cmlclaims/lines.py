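"""Construction of lines of therapy from claims — the analytical core.

A line of therapy is a maximal period on one CML-CP drug (imatinib,
dasatinib, nilotinib, bosutinib, ponatinib, or omacetaxine).  It starts at
the first claim for that drug and ends at the earliest of:

* **switch** — the first fill of a *different* CML-CP drug (the next line
  starts the same day), regardless of how long the intervening gap was;
* **apbc_chemo** — initiation of a chemotherapy not listed for CML-CP,
  signalling progression to accelerated phase / blast crisis; no later
  lines are constructed;
* **hsct** — a hematopoietic stem cell transplantation procedure; no later
  lines are constructed;
* **discontinuation** — a treatment-free period of at least ``gap_days``
  (default 90) after the last fill's supply ran out, with no further
  therapy of any kind before the end of observation; the line ends at the
  supply end;
* **censored** — the end of the observation period arrives first.

A >= ``gap_days`` gap followed by resumption of the *same* drug is a
treatment interruption (noncompliance), not a new line: it increments the
line's interruption count and the line continues.

Supply end is ``fill_date + days_supply``; gaps are measured from supply
end, so "treatment-free" time is supply-adjusted.  Same-day tie-breaks are
deterministic: HSCT > AP/BC chemotherapy > switch; when two different
CML-CP drugs are first filled on the same day, the drug with the larger
days supply defines the line (alphabetical order breaks exact ties).
"""

from __future__ import annotations

import datetime as dt
from collections import Counter
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .config import (
    CML_CP_DRUGS,
    ConfigError,
    StudyConfig,
    any_code_matches,
)
from .model import ClaimsBundle, split_codes

_KIND_PRIORITY = {"hsct": 0, "apbc_chemo": 1, "therapy_fill": 2}


@dataclass(frozen=True)
class TherapyEvent:
    """A line-relevant event: a CML-CP therapy fill or a terminal procedure."""

    patient_id: str
    date: dt.date
    kind: str  # therapy_fill | hsct | apbc_chemo
    drug: Optional[str] = None
    days_supply: int = 0

    def sort_key(self):
        return (self.date, _KIND_PRIORITY[self.kind], self.drug or "", -self.days_supply)


@dataclass
class TherapyLine:
    patient_id: str
    line_number: int
    drug: str
    start_date: dt.date
    end_date: dt.date
    supply_end_date: dt.date
    end_event: str  # switch | apbc_chemo | hsct | discontinuation | censored
    n_fills: int
    interruption_count: int
    treatment_free_days_to_next: Optional[int] = None

    def duration_months(self, month_length_days: float = 365.25 / 12) -> float:
        return (self.end_date - self.start_date).days / month_length_days


def collect_therapy_events(
    bundle_or_frames, config: StudyConfig, patient_id: Optional[str] = None
) -> list[TherapyEvent]:
    """Extract the ordered line-relevant event stream for one patient.

    Therapy fills are kept only for the six CML-CP drugs and only on/after
    the drug's earliest FDA approval date (hydroxyurea and ``other`` fills
    are never line-defining).  Omacetaxine may also appear as a
    procedure-coded medical claim.  HSCT and AP/BC chemotherapy procedures
    are included as terminal events.
    """
    if isinstance(bundle_or_frames, ClaimsBundle):
        ph = bundle_or_frames.pharmacy
        med = bundle_or_frames.medical
        if patient_id is not None:
            ph = ph[ph["patient_id"] == patient_id]
            med = med[med["patient_id"] == patient_id]
    else:
        ph, med = bundle_or_frames

    events: list[TherapyEvent] = []
    for row in ph.itertuples():
        drug = row.drug
        if drug not in CML_CP_DRUGS:
            continue
        if row.fill_date < config.approval_dates[drug].earliest:
            continue
        events.append(
            TherapyEvent(
                patient_id=row.patient_id,
                date=row.fill_date,
                kind="therapy_fill",
                drug=drug,
                days_supply=int(row.days_supply),
            )
        )
    oma_approval = config.approval_dates["omacetaxine"].earliest
    for row in med.itertuples():
        procs = split_codes(row.procedure_codes)
        if not procs:
            continue
        if any_code_matches(procs, config.codes.hsct_procedures):
            events.append(
                TherapyEvent(patient_id=row.patient_id, date=row.start_date, kind="hsct")
            )
        elif any_code_matches(procs, config.codes.ap_bc_chemo):
            events.append(
                TherapyEvent(
                    patient_id=row.patient_id, date=row.start_date, kind="apbc_chemo"
                )
            )
        elif any_code_matches(procs, config.codes.omacetaxine_procedures):
            if row.start_date >= oma_approval:
                # Administered omacetaxine: a therapy event with one day of
                # supply (an injectable, not a fill with days supply).
                events.append(
                    TherapyEvent(
                        patient_id=row.patient_id,
                        date=row.start_date,
                        kind="therapy_fill",
                        drug="omacetaxine",
                        days_supply=1,
                    )
                )
    events.sort(key=TherapyEvent.sort_key)
    return events


def _pick_defining_fill(fills: list[TherapyEvent]) -> TherapyEvent:
    """Largest days-supply defines the line; alphabetical drug breaks ties."""
    return min(fills, key=lambda f: (-f.days_supply, f.drug))


def build_lines(
    events: list[TherapyEvent],
    observation_end: dt.date,
    gap_days: int,
) -> list[TherapyLine]:
    """Scan the ordered event stream into lines of therapy.

    ``events`` must belong to one patient; they are re-sorted defensively so
    the result never depends on input order.  Events after ``observation_end``
    are ignored.  Terminal events (HSCT, AP/BC chemotherapy) occurring before
    the first therapy fill are ignored for line construction.
    """
    if gap_days <= 0:
        raise ConfigError("gap_days must be positive")
    events = sorted(
        (e for e in events if e.date <= observation_end), key=TherapyEvent.sort_key
    )
    if not events:
        return []
    pid = events[0].patient_id

    lines: list[TherapyLine] = []
    cur: Optional[TherapyLine] = None
    terminated = False

    # Group events by date to apply same-day tie-breaks deterministically.
    by_date: dict[dt.date, list[TherapyEvent]] = {}
    for e in events:
        by_date.setdefault(e.date, []).append(e)

    def open_line(fills_at_date: list[TherapyEvent], date: dt.date) -> TherapyLine:
        defining = _pick_defining_fill(fills_at_date)
        same = [f for f in fills_at_date if f.drug == defining.drug]
        supply_end = max(date + dt.timedelta(days=f.days_supply) for f in same)
        return TherapyLine(
            patient_id=pid,
            line_number=len(lines) + 1,
            drug=defining.drug,  # type: ignore[arg-type]
            start_date=date,
            end_date=date,  # provisional
            supply_end_date=supply_end,
            end_event="censored",  # provisional
            n_fills=len(same),
            interruption_count=0,
        )

    def close_line(line: TherapyLine, event: str, end: dt.date) -> None:
        line.end_event = event
        line.end_date = end
        lines.append(line)

    for date in sorted(by_date):
        if terminated:
            break
        todays = by_date[date]
        hscts = [e for e in todays if e.kind == "hsct"]
        apbcs = [e for e in todays if e.kind == "apbc_chemo"]
        fills = [e for e in todays if e.kind == "therapy_fill"]

        if cur is not None and hscts:
            close_line(cur, "hsct", date)
            cur = None
            terminated = True
            continue
        if cur is not None and apbcs:
            close_line(cur, "apbc_chemo", date)
            cur = None
            terminated = True
            continue
        if not fills:
            continue
        if cur is None:
            cur = open_line(fills, date)
            continue

        same = [f for f in fills if f.drug == cur.drug]
        diff = [f for f in fills if f.drug != cur.drug]
        if same:
            # A gap >= gap_days followed by resumption of the same drug is an
            # interruption — but not when the line ends by switch this very
            # day (no resumption takes place).
            gap = (date - cur.supply_end_date).days
            if gap >= gap_days and not diff:
                cur.interruption_count += 1
            cur.n_fills += len(same)
            cur.supply_end_date = max(
                cur.supply_end_date,
                max(date + dt.timedelta(days=f.days_supply) for f in same),
            )
        if diff:
            prev = cur
            close_line(prev, "switch", date)
            prev.treatment_free_days_to_next = max(
                0, (date - prev.supply_end_date).days
            )
            cur = open_line(diff, date)

    if cur is not None and not terminated:
        if (observation_end - cur.supply_end_date).days >= gap_days:
            close_line(cur, "discontinuation", cur.supply_end_date)
        else:
            close_line(cur, "censored", observation_end)

    return lines


def classify_generation(drug: str, config: Optional[StudyConfig] = None) -> str:
    """TKI generation token: imatinib 1G; dasatinib/nilotinib/bosutinib 2G;
    ponatinib 3G; omacetaxine (non-TKI) ``other``."""
    gen_map = (config or StudyConfig()).generation_map
    try:
        return gen_map[drug]
    except KeyError:
        raise ConfigError(f"no generation mapping for drug {drug!r}") from None


def build_lines_for_cohort(
    bundle: ClaimsBundle,
    observation_ends: dict[str, dt.date],
    config: StudyConfig,
) -> dict[str, list[TherapyLine]]:
    """Construct lines for every patient with a known observation end."""
    ph_groups = dict(tuple(bundle.pharmacy.groupby("patient_id", sort=True)))
    med_groups = dict(tuple(bundle.medical.groupby("patient_id", sort=True)))
    empty_ph = bundle.pharmacy.iloc[0:0]
    empty_med = bundle.medical.iloc[0:0]
    out: dict[str, list[TherapyLine]] = {}
    for pid in sorted(observation_ends):
        events = collect_therapy_events(
            (ph_groups.get(pid, empty_ph), med_groups.get(pid, empty_med)), config
        )
        out[pid] = build_lines(events, observation_ends[pid], config.gap_days)
    return out


# ---------------------------------------------------------------------------
# Summaries


def lines_frame(lines_by_patient: dict[str, list[TherapyLine]]) -> pd.DataFrame:
    rows = []
    for pid in sorted(lines_by_patient):
        for ln in lines_by_patient[pid]:
            rows.append(
                {
                    "patient_id": pid,
                    "line_number": ln.line_number,
                    "drug": ln.drug,
                    "start_date": ln.start_date,
                    "end_date": ln.end_date,
                    "supply_end_date": ln.supply_end_date,
                    "end_event": ln.end_event,
                    "n_fills": ln.n_fills,
                    "interruption_count": ln.interruption_count,
                    "treatment_free_days_to_next": ln.treatment_free_days_to_next,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id", "line_number", "drug", "start_date", "end_date",
            "supply_end_date", "end_event", "n_fills", "interruption_count",
            "treatment_free_days_to_next",
        ],
    )


def summarize_lines(
    lines_by_patient: dict[str, list[TherapyLine]],
    config: StudyConfig,
    max_line: int = 4,
) -> dict[int, dict]:
    """Per-line-number treatment-pattern summary.

    Durations are reported in months of ``month_length_days`` days.  The
    duration buckets use closed upper bounds (a duration of exactly 3.0
    months falls in the "<=3 mo" bucket); ">6 mo" and ">12 mo" are
    cumulative categories, with ">12 mo" a subset of ">6 mo".
    """
    mlen = config.month_length_days
    out: dict[int, dict] = {}
    for ln_no in range(1, max_line + 1):
        lines = [
            lines[ln_no - 1]
            for lines in lines_by_patient.values()
            if len(lines) >= ln_no
        ]
        if not lines:
            continue
        durations = np.array([ln.duration_months(mlen) for ln in lines])
        tf = np.array(
            [
                ln.treatment_free_days_to_next / mlen
                for ln in lines
                if ln.treatment_free_days_to_next is not None
            ]
        )
        n = len(lines)
        summary = {
            "n": n,
            "drug_counts": dict(sorted(Counter(ln.drug for ln in lines).items())),
            "generation_counts": dict(
                sorted(
                    Counter(
                        classify_generation(ln.drug, config) for ln in lines
                    ).items()
                )
            ),
            "duration_mean": float(durations.mean()),
            "duration_sd": float(durations.std(ddof=1)) if n > 1 else 0.0,
            "duration_median": float(np.median(durations)),
            "one_fill": int(sum(ln.n_fills == 1 for ln in lines)),
            "le_3mo": int((durations <= 3.0).sum()),
            "gt3_le6mo": int(((durations > 3.0) & (durations <= 6.0)).sum()),
            "gt_6mo": int((durations > 6.0).sum()),
            "gt_12mo": int((durations > 12.0).sum()),
            "treatment_free_mean": float(tf.mean()) if tf.size else None,
            "treatment_free_sd": float(tf.std(ddof=1)) if tf.size > 1 else (0.0 if tf.size else None),
            "treatment_free_median": float(np.median(tf)) if tf.size else None,
            "end_event_counts": dict(
                sorted(Counter(ln.end_event for ln in lines).items())
            ),
            "interruption_total": int(sum(ln.interruption_count for ln in lines)),
        }
        out[ln_no] = summary
    return out


def sequence_frequencies(
    lines_by_patient: dict[str, list[TherapyLine]],
    depth: int,
    config: Optional[StudyConfig] = None,
) -> pd.DataFrame:
    """Frequencies of ordered drug (and generation) tuples among patients
    reaching at least ``depth`` lines."""
    if depth < 2:
        raise ValueError("depth must be >= 2")
    config = config or StudyConfig()
    tuples = []
    for pid in sorted(lines_by_patient):
        lines = lines_by_patient[pid]
        if len(lines) >= depth:
            drugs = tuple(ln.drug for ln in lines[:depth])
            gens = tuple(classify_generation(d, config) for d in drugs)
            tuples.append((drugs, gens))
    if not tuples:
        return pd.DataFrame(columns=["sequence", "generations", "count", "frequency"])
    counts = Counter(tuples)
    total = len(tuples)
    rows = [
        {
            "sequence": " -> ".join(drugs),
            "generations": " -> ".join(gens),
            "count": c,
            "frequency": c / total,
        }
        for (drugs, gens), c in sorted(
            counts.items(), key=lambda kv: (-kv[1], kv[0])
        )
    ]
    return pd.DataFrame(rows)
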