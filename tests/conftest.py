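"""Shared fixtures: expensive simulation artifacts built once per session."""

import numpy as np
import pytest

from vancoauc import PopulationSpec, run_simulation_study
from vancoauc.clinical import generate_synthetic_cohort, run_clinical_pipeline
from vancoauc.nomogram import build_all_nomograms


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def sim_small():
    """Quick pseudo-population run for property checks."""
    return run_simulation_study(PopulationSpec(seed=11), n_draws=600)


@pytest.fixture(scope="session")
def sim_full():
    """Full-size pseudo-population study (5000 draws)."""
    return run_simulation_study(PopulationSpec(seed=1), n_draws=5000)


@pytest.fixture(scope="session")
def all_grids():
    """The 15 canonical AUC nomograms."""
    return build_all_nomograms()


@pytest.fixture(scope="session")
def cohort_pipeline():
    """Synthetic 200-patient cohort (10% proportional noise) plus the
    three-way estimation pipeline output."""
    records = generate_synthetic_cohort(200, error_cv=0.10, seed=7)
    table, report = run_clinical_pipeline(records)
    return records, table, report
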