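"""Shared fixtures.

The two session-scoped fixtures run the package's two reference studies once
per test session: the noiseless single-dipole cohort (linear-physics
exactness regime) and the full jittered multi-dipole cohort (the realistic
study conditions). Both are deterministic for their fixed seeds.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from ecgrecon.grid import GridLayout
from ecgrecon.simulate import (
    CohortConfig,
    SubjectParams,
    default_sources,
    default_torso,
    physics_oracle_config,
    simulate_subject,
)
from ecgrecon.study import StudyConfig, prepare_data, run_shape_study


@pytest.fixture(scope="session")
def grid() -> GridLayout:
    return GridLayout()


@pytest.fixture(scope="session")
def torso():
    return default_torso()


@pytest.fixture(scope="session")
def single_dipole_recording(torso):
    """Short noiseless single-dipole recording (exact linear regime)."""
    params = SubjectParams(seed=5, heart_rate=70.0)
    return simulate_subject(
        params, torso, duration_s=10.0, fs=250.0, sources=default_sources("single")
    )


@pytest.fixture(scope="session")
def physics_study():
    """MLR study on the noiseless single-dipole cohort, all shape families."""
    cfg = StudyConfig(cohort=physics_oracle_config(123), models=("mlr",))
    data = prepare_data(cfg)
    return cfg, data, run_shape_study(cfg, data, keep_models=False)


@pytest.fixture(scope="session")
def full_study():
    """The realistic study: 14-subject jittered multi-dipole cohort,
    MLR + 5-seed ANN ensembles over the 99 shape-family combinations."""
    cfg = StudyConfig()
    data = prepare_data(cfg)
    return cfg, data, run_shape_study(cfg, data, keep_models=False)


@pytest.fixture()
def small_multi_cohort_config():
    """Reduced multi-dipole cohort for fast structural tests."""
    return CohortConfig(n_subjects=3, duration_s=40.0, master_seed=7)


@pytest.fixture()
def small_study_config(small_multi_cohort_config):
    return StudyConfig(
        cohort=small_multi_cohort_config,
        models=("mlr",),
        families=("square5", "triangle"),
    )
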