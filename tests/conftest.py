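"""Shared fixtures: the default panel, the packaged composition config, and a
session-cached full pipeline run of the three study comparisons (kept at a
reduced grid so the suite stays fast; the generator's statistical structure is
unchanged)."""

from __future__ import annotations

import numpy as np
import pytest

from glioims.lipid_chem import default_panel
from glioims.pipeline import run_lipidomics_comparison
from glioims.synth_data import (
    default_study_spec,
    make_study_config,
    simulate_expression_study,
)


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def study_config(panel):
    profiles, noise, study_spec = make_study_config(panel)
    return profiles, noise, study_spec


@pytest.fixture(scope="session")
def study_run(panel):
    """Full pipeline on the packaged study design: 5 sections per arm,
    negative-ion mode, noise sigma 0.3 and 3 ppm jitter, seeds 1-5 per arm."""
    grid = (44, 44)
    comp_gbm, arms = run_lipidomics_comparison(
        "healthy_vehicle", "gbm_vehicle",
        n_sections=5, grid=grid, seed=1, panel=panel,
    )
    comp_tmz, arms = run_lipidomics_comparison(
        "healthy_vehicle", "healthy_tmz",
        n_sections=5, grid=grid, seed=1, panel=panel, arm_results=arms,
    )
    return {"gbm_vs_healthy": comp_gbm, "tmz_vs_vehicle": comp_tmz,
            "arms": arms}


@pytest.fixture(scope="session")
def study():
    """One realisation of the planted expression/methylation/survival study."""
    return simulate_expression_study(default_study_spec(seed=11))


@pytest.fixture(scope="session")
def null_study():
    """Same design with zero planted effect."""
    return simulate_expression_study(default_study_spec(effect=0.0, seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
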