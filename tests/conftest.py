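import numpy as np
import pytest

from radtrap.core import VolumeGrid
from radtrap.phantom import PhantomSpec, make_phantom_case


@pytest.fixture(scope="session")
def default_case():
    """One full phantom case at the default study conditions."""
    return make_phantom_case(PhantomSpec(seed=11))


@pytest.fixture(scope="session")
def mpmri_case():
    """A second, independent mpMRI-only phantom (small grids, fast)."""
    from radtrap.phantom import generate_mpmri_phantom

    t2w, adc, st = generate_mpmri_phantom(PhantomSpec(seed=23))
    return t2w, adc, st


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def small_volume(rng):
    """A 20x18x6 noise volume with anisotropic spacing."""
    vals = rng.normal(100.0, 15.0, size=(20, 18, 6))
    return VolumeGrid(vals, (1.0, 1.25, 3.0), (-10.0, -11.25, -9.0))
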