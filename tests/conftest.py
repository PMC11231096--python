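import dataclasses

import numpy as np
import pytest

from dynb0 import (Protocol, acquire_calibration, make_coil_maps, make_phantom,
                   make_task_events, sigma_for_snr)
from dynb0.calib import train_operators


@pytest.fixture(scope="session")
def protocol():
    """Noiseless default protocol (64x64, 4 slices, 8 coils, MB=2, R=2)."""
    return Protocol(sigma=0.0)


@pytest.fixture(scope="session")
def phantom(protocol):
    return make_phantom(protocol.n, protocol.n_slices, seed=1)


@pytest.fixture(scope="session")
def coils(protocol, phantom):
    return make_coil_maps(protocol.n_coils, protocol.n, seed=1)


@pytest.fixture(scope="session")
def calibration(phantom, coils, protocol):
    return acquire_calibration(phantom, coils, protocol, seed=0)


@pytest.fixture(scope="session")
def operators(calibration, protocol):
    return train_operators(calibration.calib, protocol)


@pytest.fixture(scope="session")
def noisy_protocol(protocol, phantom, coils):
    """Protocol with noise giving coil-combined image SNR ~ 30."""
    sigma = sigma_for_snr(phantom, coils, protocol, 30.0)
    return dataclasses.replace(protocol, sigma=sigma)


@pytest.fixture(scope="session")
def events():
    return make_task_events(12, 0.8, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
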