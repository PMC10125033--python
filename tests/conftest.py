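import numpy as np
import pytest

import oridisc as od
from oridisc.energy import EnergyMatrix
from oridisc.schedule import DEFAULT_LEVEL_SET

LOW_LEVELS = DEFAULT_LEVEL_SET[DEFAULT_LEVEL_SET < 20.0]


@pytest.fixture(scope="session")
def spec64():
    """Desk-scale stimulus spec: 64 px, 2.5 degree field at 25.6 px/degree."""
    return od.StimulusSpec(image_size_px=64, pixels_per_degree=25.6,
                           n_images=26)


@pytest.fixture(scope="session")
def interleaved_session(spec64):
    """One interleaved low-signal session: 2,500 trials + standardized
    orientation-energy regressors (shared across behavioral tests)."""
    trials = od.gen_trial_schedule(2500, seed=60, level_set=LOW_LEVELS)
    energy = od.energy_for_trials(trials, spec64, n_reference=300, seed=61)
    return trials, energy


def subset_session(trials, energy, n):
    """First-n-trials view of a session (trial table + energy)."""
    en = EnergyMatrix(S=energy.S[:n], u=energy.u[:n],
                      reference_mean=energy.reference_mean,
                      reference_sd=energy.reference_sd)
    return trials.iloc[:n].reset_index(drop=True), en


@pytest.fixture(scope="session")
def session_800(interleaved_session):
    trials, energy = interleaved_session
    return subset_session(trials, energy, 800)


@pytest.fixture(scope="session")
def subset():
    """The subset helper as a fixture (keeps tests import-path agnostic)."""
    return subset_session
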