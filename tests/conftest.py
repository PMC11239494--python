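import numpy as np
import pytest

from lamicro import synthetic
from lamicro.types import DistanceProfile, ProtocolSpec, QuantalParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def quantal_truth():
    """Ground-truth release parameters in the fitting regime of interest."""
    return QuantalParams(
        n_sites=5, p_release=0.5, q_size=460.0, sigma_noise=30.0, variance_model="type1"
    )


@pytest.fixture
def step_profile():
    """Connection probability falling off over 300 µm in 100-µm bins."""
    return DistanceProfile((0.0, 100.0, 200.0, 300.0), (0.10, 0.05, 0.02))


@pytest.fixture
def protocol():
    return ProtocolSpec()


@pytest.fixture
def planted_sweeps():
    """A probed pair with an 800-µV EPSP at 2-ms latency in 20-µV noise."""
    conn = synthetic.SyntheticConnection(latency_ms=2.0, amplitude_uv=800.0)
    return synthetic.simulate_sweep_set(conn, noise_sd_uv=20.0, seed=3)
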