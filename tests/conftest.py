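import numpy as np
import pytest

from nirsdot.array_registration import bright_array_spec
from nirsdot.synthetic_data import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def phantom():
    """Default ellipsoid four-layer phantom (landmark frame)."""
    return make_phantom()


@pytest.fixture(scope="session")
def sphere_phantom():
    """Spherical phantom, radius 70 mm, for analytic geometry checks."""
    return make_phantom(PhantomSpec(semi_axes=(70.0, 70.0, 70.0)))


@pytest.fixture(scope="session")
def array_spec():
    return bright_array_spec()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
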