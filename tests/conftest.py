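import numpy as np
import pytest
from hypothesis import settings

from outcomesurf.surfstats import build_icosphere

settings.register_profile("default", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def mesh_ico2():
    """162-vertex sphere, radius 100 mm: cheap topology/arithmetic checks."""
    return build_icosphere(2, 100.0)


@pytest.fixture(scope="session")
def mesh_ico3():
    """642-vertex sphere, radius 100 mm."""
    return build_icosphere(3, 100.0)


@pytest.fixture(scope="session")
def mesh_ico4():
    """2562-vertex sphere, radius 100 mm: the cohort-generator default."""
    return build_icosphere(4, 100.0)


@pytest.fixture(scope="session")
def mesh_ico4_fine():
    """2562 vertices on a radius-20 sphere: vertex spacing ≈ 1.4 mm, so a
    10-mm-FWHM field is oversampled ~7×, which continuum random-field theory
    needs to be accurate on a lattice."""
    return build_icosphere(4, 20.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
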