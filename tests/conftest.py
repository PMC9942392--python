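"""Shared fixtures: synthetic cohorts and fitted pipelines.

Everything is generated programmatically with fixed seeds; the session-
scoped pipeline fit is reused across dynamic-prediction and evaluation
tests to keep the suite fast.
"""

import numpy as np
import pandas as pd
import pytest

from trajsurv.pipeline import PipelineSettings, fit_pipeline
from trajsurv.simulate import CohortConfig, SpikeSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    cfg = CohortConfig(n_patients=300, seed=7)
    patients, measurements, truth = generate_cohort(cfg)
    return patients, measurements, truth


@pytest.fixture(scope="session")
def clean_cohort():
    """No spikes: data follow the two-component model exactly."""
    cfg = CohortConfig(n_patients=400, seed=21, spikes=SpikeSpec(prob=0.0))
    patients, measurements, truth = generate_cohort(cfg)
    return patients, measurements, truth


@pytest.fixture(scope="session")
def fitted(small_cohort):
    patients, measurements, _ = small_cohort
    settings = PipelineSettings(n_estimators=150)
    fp = fit_pipeline(
        measurements, patients,
        configs=["preop_3marker", "longitudinal_3marker"],
        settings=settings, seed=11)
    return fp, patients, measurements


@pytest.fixture()
def hand_cohort():
    """Eight patients with hand-set survival data around s=12, t=36."""
    return pd.DataFrame({
        "time_months": [14.0, 20.0, 25.0, 30.0, 33.0, 40.0, 55.0, 80.0],
        "event":       [1,    0,    1,    1,    0,    0,    1,    0],
        "risk":        [0.9,  0.2,  0.7,  0.55, 0.4,  0.35, 0.6,  0.1],
    })


def rng(seed=0):
    return np.random.default_rng(seed)
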