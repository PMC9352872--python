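"""Shared fixtures: study config and simulated populations (session-scoped,
generated programmatically — no data files)."""

from __future__ import annotations

import pytest

from cmlclaims.cohort import apply_selection
from cmlclaims.config import StudyConfig
from cmlclaims.simulate import TrajectorySpec, generate_cohort


@pytest.fixture(scope="session")
def config() -> StudyConfig:
    return StudyConfig()


@pytest.fixture(scope="session")
def small_population(config):
    """A mixed population with the natural line-count distribution and
    engineered exclusion modes."""
    spec = TrajectorySpec(n_patients=150, seed=5)
    return generate_cohort(spec, config)


@pytest.fixture(scope="session")
def cohort_3l(config):
    """A population where every patient reaches at least three lines, with
    terminal HSCT / AP-BC events enabled — the workhorse for outcome tests."""
    spec = TrajectorySpec(
        n_patients=350,
        seed=11,
        line_count_distribution={3: 0.72, 4: 0.28},
        p_hsct_final_3l=0.12,
        p_apbc_final_3l=0.08,
        p_enrollment_gap=0.0,
        p_remission_code=0.0,
        p_trial_code=0.0,
        p_late_1l=0.0,
    )
    bundle, truth = generate_cohort(spec, config)
    selection = apply_selection(bundle, config)
    return bundle, truth, selection


@pytest.fixture(scope="session")
def grouped_claims(cohort_3l):
    bundle, _, _ = cohort_3l
    ph = {pid: df for pid, df in bundle.pharmacy.groupby("patient_id", sort=True)}
    med = {pid: df for pid, df in bundle.medical.groupby("patient_id", sort=True)}
    return ph, med
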