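import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260918)


@pytest.fixture(scope="session")
def small_channel():
    """Tiny rectangular channel with a floor patch (fast tests)."""
    from thrombosim import geometry

    return geometry.build_channel(
        length=150.0, width=50.0, height=40.0,
        patch_start=50.0, patch_length=50.0, h=5.0, tf_on=True,
    )


@pytest.fixture(scope="session")
def small_tube():
    from thrombosim import geometry

    return geometry.build_tube(
        length=100.0, diameter=40.0, patch_arc_fraction=0.5,
        patch_length=50.0, h=2.5, tf_on=True,
    )
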