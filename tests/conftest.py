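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
def head_phantom():
    from fansym.phantom import default_head_phantom

    return default_head_phantom()


@pytest.fixture(scope="session")
def head_sinogram(head_phantom):
    """Analytic sinogram of the head phantom at a small, fast geometry."""
    from fansym.projection import FanBeamGeometry, project_analytic

    geom = FanBeamGeometry.for_object(head_phantom.bounding_radius, 120, 129)
    return project_analytic(head_phantom, geom)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
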