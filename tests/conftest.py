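import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", deadline=None, derandomize=True)
settings.load_profile("default")

from mazepoint.alternative_model import alternative_route
from mazepoint.geometry import realize_layout, reference_layout, reference_route


@pytest.fixture(scope="session")
def route():
    return reference_route()


@pytest.fixture(scope="session")
def layout():
    return reference_layout()


@pytest.fixture(scope="session")
def alt_layout(route):
    return realize_layout(alternative_route(route))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240)


def vonmises_deg(rng, mu_deg, kappa, size):
    """Von Mises draws in azimuth degrees."""
    return np.degrees(rng.vonmises(np.radians(mu_deg), kappa, size)) % 360.0
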