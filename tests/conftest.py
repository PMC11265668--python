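import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240711)


@pytest.fixture
def small_rd_params():
    """Cheap but non-trivial run configuration for integration tests."""
    from markspread import RDParams

    return RDParams(
        n_nucleosomes=21,
        radius=12.0,
        n_enzymes=80,
        n_steps=20_000,
        burn_in=5_000,
        sample_interval=100,
        seed=7,
    )
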