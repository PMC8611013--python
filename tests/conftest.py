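"""Shared fixtures.

Heavy end-to-end artifacts (water calibrations, trained decomposition
models, demo pipelines) are session-scoped and computed lazily, so every
test that needs e.g. the liver replicates shares one simulation.

Problem sizes: unit tests run on a minimal geometry (240 views, 384
native columns, 160×160 reconstruction); integration and acceptance
tests use the reduced desk-scale profile (720 views, 768 columns,
313×313) whose fan coverage and binned detector sampling match the
full-scale system.
"""

import numpy as np
import pytest
from hypothesis import settings

from pcct.geometry import TINY_GEOMETRY
from pcct.pipeline import (
    RunProfile,
    profile_water_calibration,
    reduced_profile,
    run_brain_demo,
    run_hu_comparison_demo,
    run_liver_demo,
    run_resolution_demo,
    train_on_inserts,
)

settings.register_profile("suite", deadline=None, max_examples=25,
                          derandomize=True)
settings.load_profile("suite")

MASTER_SEED = 20260923


@pytest.fixture(scope="session")
def tiny_profile():
    return RunProfile(geometry=TINY_GEOMETRY, recon_n=160)


@pytest.fixture(scope="session")
def tiny_water_cal(tiny_profile):
    return profile_water_calibration(tiny_profile)


@pytest.fixture(scope="session")
def profile():
    return reduced_profile()


@pytest.fixture(scope="session")
def water_cal(profile):
    return profile_water_calibration(profile)


@pytest.fixture(scope="session")
def noiseless_insert_run(profile, water_cal):
    """Noiseless insert-phantom acquisition + trained model."""
    model, loss, info = train_on_inserts(
        profile, MASTER_SEED, water_cal, noiseless=True)
    return {"model": model, "loss": loss, **info}


@pytest.fixture(scope="session")
def noisy_insert_run(profile, water_cal):
    """Full-dose noisy insert-phantom acquisition + trained model."""
    model, loss, info = train_on_inserts(
        profile, MASTER_SEED + 1, water_cal, noiseless=False)
    return {"model": model, "loss": loss, **info}


@pytest.fixture(scope="session")
def liver_results(profile, water_cal, noisy_insert_run):
    return run_liver_demo(profile, MASTER_SEED, water_cal=water_cal,
                          model=noisy_insert_run["model"])


@pytest.fixture(scope="session")
def brain_results(profile, water_cal):
    return run_brain_demo(profile, MASTER_SEED, water_cal=water_cal)


@pytest.fixture(scope="session")
def hu_comparison_results(profile):
    return run_hu_comparison_demo(profile, MASTER_SEED)


@pytest.fixture(scope="session")
def resolution_results():
    return run_resolution_demo(MASTER_SEED)


@pytest.fixture(scope="session")
def spectrum140():
    from pcct.physics import generate_tube_spectrum

    return generate_tube_spectrum(140.0, (("aluminium", 2.5),), 1.0)
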