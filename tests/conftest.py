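import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cardiokymo as ck

settings.register_profile(
    "suite", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def protocol_1hz() -> ck.StimulusProtocol:
    return ck.StimulusProtocol(frequency_hz=1.0)


@pytest.fixture(scope="session")
def clean_record(protocol_1hz):
    """A strictly noise-free default-cell record (no shot/read noise, no
    quantization) with its analytic ground truth."""
    return ck.simulate_cell_record(
        ck.CellTruth(), ck.EndpointGains(), protocol_1hz, seed=1,
        shot_noise=False, read_noise_sd=0.0, quantize=False)


@pytest.fixture(scope="session")
def noisy_record(protocol_1hz):
    """A default-cell record with the full noise model."""
    return ck.simulate_cell_record(
        ck.CellTruth(), ck.EndpointGains(), protocol_1hz, seed=7)


@pytest.fixture(scope="session")
def noisy_float_record(protocol_1hz):
    """Full noise model but no uint16 quantization (float image), so pure
    multiplicative intensity re-scalings are exactly representable."""
    return ck.simulate_cell_record(
        ck.CellTruth(), ck.EndpointGains(), protocol_1hz, seed=7,
        quantize=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
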