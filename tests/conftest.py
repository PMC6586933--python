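import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_recording():
    """60-cell default-condition synthetic recording shared across tests."""
    from calslice import default_config, generate_recording

    return generate_recording(default_config(n_cells=60, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
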