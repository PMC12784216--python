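import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", max_examples=50, deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_subject():
    from septrial import synth
    return synth.calibrate_subject(synth.TABLE_TARGET_INTENSITY)


@pytest.fixture(scope="session")
def noiseless_session(default_subject):
    """Small noise-free session at the 1 ms condition (shared, read-only)."""
    from septrial import synth
    protocol = synth.StimulationProtocol(n_trials=12)
    return synth.synth_eeg_session(default_subject, protocol, 1.0, seed=0,
                                   noiseless=True)


@pytest.fixture(scope="session")
def noisy_session(default_subject):
    """Default-noise session at the 1 ms condition (shared, read-only)."""
    from septrial import synth
    protocol = synth.StimulationProtocol(n_trials=70)
    return synth.synth_eeg_session(default_subject, protocol, 1.0, seed=42,
                                   include_emg=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
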