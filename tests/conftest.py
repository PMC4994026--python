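"""Shared fixtures.

The ``recovery_study`` fixture is the one expensive object in the suite: a
15 + 15 subject synthetic study on the reduced single-hemisphere network,
inverted end to end.  It is session-scoped and shared by the acceptance
tests and the end-to-end recovery checks.
"""

from __future__ import annotations

import pytest

from microdcm import (
    CMCParameters,
    SimulationGrid,
    StimulusInput,
    build_model,
)
from microdcm.analysis_pipeline import StudyOptions, run_study
from microdcm.synthetic_data import CohortSpec, generate_cohort

REDUCED = ("L",)
STUDY_SEED = 101


@pytest.fixture(scope="session")
def grid() -> SimulationGrid:
    return SimulationGrid()


@pytest.fixture(scope="session")
def stimulus() -> StimulusInput:
    return StimulusInput()


@pytest.fixture(scope="session")
def cmc() -> CMCParameters:
    return CMCParameters()


@pytest.fixture(scope="session")
def reduced_models():
    return [build_model(i, REDUCED) for i in (1, 2, 3)]


@pytest.fixture(scope="session")
def recovery_cohorts():
    """15-subject older-like and younger-like cohorts (reduced network)."""
    return {
        group: generate_cohort(
            CohortSpec(group=group, n_subjects=15, hemispheres=REDUCED,
                       seed=STUDY_SEED, snr=5.0)
        )
        for group in ("older", "younger")
    }


@pytest.fixture(scope="session")
def recovery_study(recovery_cohorts):
    """Full pipeline run on the recovery cohorts, with details."""
    options = StudyOptions(
        hemispheres=REDUCED, max_iter=32, seed=7, n_bms_samples=1_000_000
    )
    report, details = run_study(
        {g: c.datasets for g, c in recovery_cohorts.items()},
        {g: c.behavior for g, c in recovery_cohorts.items()},
        options,
        return_details=True,
    )
    return {
        "report": report,
        "details": details,
        "cohorts": recovery_cohorts,
        "options": options,
    }
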