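"""Publication-style tables, cell suppression, and the end-to-end pipeline.

Percentages are rendered with exactly one decimal, rounding half-up (so
192/296 -> "64.9").  When suppression is enabled, displayed counts below
the threshold (default 11, the CMS small-cell policy for Medicare-derived
output) are masked; a percentage derived from a masked count is masked
too, and complementary cells are masked whenever a hidden value could be
recovered by subtraction from displayed totals.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
import time
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

from .baseline import baseline_table
from .cohort import SelectionResult, apply_selection
from .config import StudyConfig
from .costs import cost_summary, hsct_event_table
from .hru import hru_summary
from .io import read_claims_bundle, write_claims_bundle
from .lines import lines_frame, sequence_frequencies, summarize_lines
from .model import ClaimsBundle
from .simulate import GroundTruth, TrajectorySpec, generate_cohort

logger = logging.getLogger("cmlclaims")

MASK = "<suppressed>"
ABSENT = "NA"


def format_percent(numerator: int, denominator: int) -> Optional[str]:
    """``100 * numerator / denominator`` rounded half-up to one decimal.

    Returns None (an absent marker) for a zero denominator.
    """
    if denominator == 0:
        return None
    value = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    return str(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def apply_suppression(
    counts: Mapping[str, int],
    threshold: int,
    total_shown: bool = True,
) -> dict[str, str]:
    """Mask small cells in one group of counts that share a displayed total.

    Counts in ``[1, threshold - 1]`` are masked.  Zero is displayable.  If
    the group's total is displayed and exactly one cell is masked, its value
    could be recovered by subtraction, so the smallest remaining displayable
    cell (zero included) is masked as well — two masked cells make the split
    ambiguous.  A single-cell group with a public total cannot be protected
    by masking; callers must hide such totals.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    masked = {k: 1 <= v < threshold for k, v in counts.items()}
    if total_shown and sum(masked.values()) == 1:
        candidates = [k for k, v in counts.items() if not masked[k]]
        if candidates:
            extra = min(candidates, key=lambda k: (counts[k], k))
            masked[extra] = True
    return {k: MASK if masked[k] else str(v) for k, v in counts.items()}


@dataclass
class CohortReport:
    attrition: pd.DataFrame
    baseline: pd.DataFrame
    line_summary: dict[int, dict]
    line_table: pd.DataFrame
    sequences: pd.DataFrame
    hru: pd.DataFrame
    costs_main: pd.DataFrame
    costs_sensitivity: pd.DataFrame
    hsct_events: pd.DataFrame
    suppressed: bool = False
    manifest: dict = field(default_factory=dict)


def _suppress_frame(df: pd.DataFrame, count_cols: list[str], threshold: int) -> pd.DataFrame:
    out = df.copy()
    for col in count_cols:
        if col in out.columns:
            out[col] = out[col].map(
                lambda v: MASK
                if pd.notna(v) and 1 <= int(v) < threshold
                else ("" if pd.isna(v) else str(int(v)))
            )
    return out


def _line_summary_frame(summary: dict[int, dict]) -> pd.DataFrame:
    rows = []
    for ln_no in sorted(summary):
        s = summary[ln_no]
        row = {"line_number": ln_no, "n": s["n"]}
        for key in (
            "duration_mean", "duration_sd", "duration_median",
            "one_fill", "le_3mo", "gt3_le6mo", "gt_6mo", "gt_12mo",
            "treatment_free_mean", "treatment_free_sd", "treatment_free_median",
            "interruption_total",
        ):
            row[key] = s[key]
        for drug, c in s["drug_counts"].items():
            row[f"drug_{drug}"] = c
        for gen, c in s["generation_counts"].items():
            row[f"generation_{gen}"] = c
        for ev, c in s["end_event_counts"].items():
            row[f"end_{ev}"] = c
        rows.append(row)
    return pd.DataFrame(rows)


def build_report(
    bundle: ClaimsBundle,
    config: StudyConfig,
    selection: Optional[SelectionResult] = None,
    suppress: bool = False,
) -> CohortReport:
    """Assemble every study output for one population."""
    t0 = time.perf_counter()
    if selection is None:
        selection = apply_selection(bundle, config)
    cohort = selection.cohort_ids
    logger.info("[cohort] %d of %d patients selected", len(cohort), len(selection.patients))

    lines_by_patient = {
        pid: selection.patients[pid].lines for pid in cohort
    }
    summary = summarize_lines(lines_by_patient, config)
    seqs = sequence_frequencies(lines_by_patient, depth=3, config=config) if cohort else pd.DataFrame()
    logger.info("[lines] summarized %d cohort members", len(cohort))

    ph_groups = {
        pid: df for pid, df in bundle.pharmacy.groupby("patient_id", sort=True)
    }
    med_groups = {
        pid: df for pid, df in bundle.medical.groupby("patient_id", sort=True)
    }
    hru = hru_summary(med_groups, selection.patients, cohort, config)
    costs_main = cost_summary(ph_groups, med_groups, selection.patients, cohort, config)
    costs_sens = cost_summary(
        ph_groups, med_groups, selection.patients, cohort, config, exclude_hsct=True
    )
    hsct_ev = hsct_event_table(med_groups, cohort, config)
    base = baseline_table(bundle, selection.patients, cohort, config)
    logger.info("[outcomes] HRU, cost and baseline tables computed")

    attrition = selection.attrition.to_frame()
    if suppress:
        thr = config.suppression_threshold
        attrition = _suppress_frame(attrition, ["n_remaining", "n_excluded"], thr)
        base = _suppress_frame(base, ["count"], thr)

    report = CohortReport(
        attrition=attrition,
        baseline=base,
        line_summary=summary,
        line_table=lines_frame(lines_by_patient),
        sequences=seqs,
        hru=hru,
        costs_main=costs_main,
        costs_sensitivity=costs_sens,
        hsct_events=hsct_ev,
        suppressed=suppress,
        manifest={
            "n_input_patients": len(selection.patients),
            "n_cohort": len(cohort),
            "suppressed": suppress,
            "elapsed_seconds": round(time.perf_counter() - t0, 3),
        },
    )
    return report


def write_report(report: CohortReport, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.attrition.to_csv(out / "attrition.csv", index=False)
    report.baseline.to_csv(out / "baseline.csv", index=False)
    _line_summary_frame(report.line_summary).to_csv(out / "line_summary.csv", index=False)
    report.line_table.to_csv(out / "lines.csv", index=False)
    report.sequences.to_csv(out / "sequences.csv", index=False)
    report.hru.to_csv(out / "hru.csv", index=False)
    report.costs_main.to_csv(out / "costs_main.csv", index=False)
    report.costs_sensitivity.to_csv(out / "costs_sensitivity_no_hsct.csv", index=False)
    report.hsct_events.to_csv(out / "hsct_events.csv", index=False)
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(report.manifest, fh, indent=2, sort_keys=True)


def run_pipeline(
    config: StudyConfig,
    input_paths: Optional[Mapping[str, str | Path]] = None,
    simulate_spec: Optional[TrajectorySpec] = None,
    out_dir: Optional[str | Path] = None,
    suppress: bool = False,
) -> tuple[CohortReport, ClaimsBundle, Optional[GroundTruth]]:
    """simulate/ingest -> cohort -> lines -> baseline -> outcomes -> report.

    Exactly one of ``input_paths`` / ``simulate_spec`` must be given.  With
    a fixed simulation seed the written artifacts are byte-identical across
    runs.
    """
    if (input_paths is None) == (simulate_spec is None):
        raise ValueError("provide exactly one of input_paths or simulate_spec")
    truth: Optional[GroundTruth] = None
    if simulate_spec is not None:
        logger.info("[simulate] generating %d patients (seed %d)",
                    simulate_spec.n_patients, simulate_spec.seed)
        bundle, truth = generate_cohort(simulate_spec, config)
    else:
        result = read_claims_bundle(input_paths, config)
        for d in result.diagnostics:
            logger.warning("[ingest] %s row %d rejected: %s", d.table, d.line, d.message)
        bundle = result.bundle
    report = build_report(bundle, config, suppress=suppress)
    if out_dir is not None:
        write_report(report, out_dir)
        if simulate_spec is not None:
            write_claims_bundle(bundle, Path(out_dir) / "claims")
    return report, bundle, truth
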