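import numpy as np
import pytest

from oceanhsrl import IOPProfile, LidarConfig, forward_analytic, simulate_mc


@pytest.fixture(scope="session")
def config():
    return LidarConfig()


@pytest.fixture(scope="session")
def l3_profile():
    return IOPProfile.homogeneous(0.078, 0.40, 3.35, max_depth=30)


@pytest.fixture(scope="session")
def l3_signals(l3_profile, config):
    """Noiseless analytic signals for the mid-turbidity water."""
    return forward_analytic(l3_profile, config)


@pytest.fixture(scope="session")
def clear_profile():
    # particulate-free seawater: b equals the pure-water value
    return IOPProfile.homogeneous(0.042, 0.0022, 3.5, max_depth=30)


@pytest.fixture(scope="session")
def clear_mc(clear_profile, config):
    return simulate_mc(clear_profile, config, n_photons=400_000, seed=11)


@pytest.fixture(scope="session")
def l5_profile():
    return IOPProfile.homogeneous(0.047, 0.25, 3.42, max_depth=20)


@pytest.fixture(scope="session")
def l5_mc(l5_profile, config):
    return simulate_mc(l5_profile, config, n_photons=600_000, seed=7)
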