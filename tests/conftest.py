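"""Shared fixtures: synthetic clones and processed histograms.

Everything is generated at test time from seeded generators; session scope
keeps the expensive steady-state solves shared across tests.
"""

import numpy as np
import pytest

from burstflow import cytometry, simulate
from burstflow.params import BurstCoordinates, CalibrationConstants


@pytest.fixture(scope="session")
def calib():
    return CalibrationConstants()


@pytest.fixture(scope="session")
def bursting_truth():
    """A bright bursting-regime clone: large bursts, short active duration."""
    return BurstCoordinates(b=20.0, kappa_a=0.8, tau=0.02)


@pytest.fixture(scope="session")
def bursting_clone(bursting_truth, calib):
    return simulate.simulate_clone(
        bursting_truth, calib=calib, n_events=10_000, seed=42, clone_id="bursting"
    )


@pytest.fixture(scope="session")
def af_events():
    return simulate.generate_autofluorescence(n_events=10_000, seed=7)


@pytest.fixture(scope="session")
def af_hist(af_events):
    return cytometry.process_clone(af_events, gate=0.6, smooth_cutoff=16, seed=2)


@pytest.fixture(scope="session")
def data_hist(bursting_clone):
    return cytometry.process_clone(bursting_clone.events, gate=0.6, smooth_cutoff=16, seed=1)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)
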