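import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from readnet import SyntheticCohortSpec, make_block_design

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def schedule():
    return make_block_design()


@pytest.fixture(scope="session")
def small_spec():
    """Two subjects per group: cheap but structurally complete."""
    return SyntheticCohortSpec(n_per_group=2, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
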