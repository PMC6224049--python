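"""Shared fixtures.

The expensive end-to-end objects (the calibrated three-condition study and
its long-horizon PRS run) are session-scoped so the whole suite pays for
them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from coroloop.pipeline import run_long_prs, run_study
from coroloop.scenarios import run_condition, without_broadcast
from coroloop.synthetic_data import NoiseSpec, SyntheticPatientSpec

STUDY_SEED = 42


@pytest.fixture(scope="session")
def patient() -> SyntheticPatientSpec:
    return SyntheticPatientSpec(seed=STUDY_SEED)


@pytest.fixture(scope="session")
def noiseless_patient() -> SyntheticPatientSpec:
    return SyntheticPatientSpec(seed=STUDY_SEED, noise=NoiseSpec(0.0, 0.0, 0.0))


@pytest.fixture(scope="session")
def study(patient):
    """Full calibrated Rest / Stress / PRS study (the expensive fixture)."""
    return run_study(patient)


@pytest.fixture(scope="session")
def long_prs(study):
    """Long-horizon PRS run: ~3 minutes of model time, fresh hunger."""
    return run_long_prs(study, n_cycles=300)


@pytest.fixture(scope="session")
def stress_no_broadcast(study):
    """Stress rerun with the P_v broadcast disabled, controller frozen."""
    model = without_broadcast(study.models["Stress"])
    result, log, _ = run_condition(
        model, study.specs["Stress"], study.oxygen, controller_on=False,
        initial_state=study.results["Stress"].states[-1].copy(), tol=2e-3)
    return result, model


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
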