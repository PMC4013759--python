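import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import sod1mri as s

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def noise_free_spec() -> s.PhantomSpec:
    """End-stage phantom with two injected clusters, no noise."""
    return s.PhantomSpec(
        mpio_clusters=(
            s.ClusterSpec(center=(2.4, 2.4, 2.4), size=8, depth=0.4),
            s.ClusterSpec(center=(4.0, 2.4, 2.4), size=30, depth=0.4),
        ),
        noise_model="none",
        seed=7,
    )


@pytest.fixture(scope="session")
def noise_free_phantom(noise_free_spec):
    return s.generate_mri_phantom(noise_free_spec)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
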