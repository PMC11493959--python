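"""Shared fixtures: all test data is generated programmatically.

The expensive fixtures are session-scoped: a small cohort on the mini
tiling for model/behaviour tests, and one full-scale run of the default
synthetic cohort for the recovery checks.
"""

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

from delfitf import (
    SimulationConfig,
    build_healthy_panel,
    featurize_cohort,
    mini_tiling,
    simulate_cohort,
)
from delfitf.model import lopo_cv, train
from delfitf.tiling import hg19_tiling


@dataclass
class PipelineRun:
    tiling: object
    config: SimulationConfig
    cohort: object
    panel: object
    features: pd.DataFrame
    profiles: np.ndarray


def run_pipeline(config, tiling) -> PipelineRun:
    cohort = simulate_cohort(config, tiling)
    panel = build_healthy_panel(
        cohort.panel_counts, tiling, min_samples=min(20, config.n_panel)
    )
    feats, profiles = featurize_cohort(cohort.feature_inputs(), tiling, panel)
    return PipelineRun(tiling, config, cohort, panel, feats, profiles)


SMALL_CONFIG = dict(
    n_patients=8, draws_per_patient=3, coverage=300_000, n_panel=20, n_altered_arms=4
)


@pytest.fixture(scope="session")
def mini6():
    return mini_tiling(6)


@pytest.fixture(scope="session")
def small_run(mini6) -> PipelineRun:
    """Small cohort on the 6-chromosome mini tiling (seconds, not minutes)."""
    return run_pipeline(SimulationConfig(seed=11, **SMALL_CONFIG), mini6)


@pytest.fixture(scope="session")
def small_model(small_run):
    return train(small_run.features, small_run.profiles, small_run.panel, seed=11)


@pytest.fixture(scope="session")
def hg19():
    return hg19_tiling()


@pytest.fixture(scope="session")
def default_run(hg19) -> PipelineRun:
    """The default synthetic cohort (60 patients x 4 draws, seed 1) at full scale."""
    return run_pipeline(SimulationConfig(seed=1), hg19)


@pytest.fixture(scope="session")
def default_cv_scores(default_run):
    return lopo_cv(
        default_run.features, default_run.profiles, default_run.panel, seed=1
    )


@pytest.fixture(scope="session")
def default_model(default_run):
    """Locked model trained on every labeled sample of the default cohort."""
    return train(default_run.features, default_run.profiles, default_run.panel, seed=1)
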