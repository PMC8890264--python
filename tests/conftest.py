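import numpy as np
import pytest

from gridmol.atom_types import AtomProperty, TypeScheme, default_scheme
from gridmol.grids import GridSpec


@pytest.fixture(scope="session")
def lig_scheme():
    return default_scheme("ligand")


@pytest.fixture(scope="session")
def rec_scheme():
    return default_scheme("receptor")


@pytest.fixture(scope="session")
def single_channel_scheme():
    """Carbon-only, element-block-only scheme for toy-grid oracles."""
    return TypeScheme(role="ligand", properties=(AtomProperty("element", ("C",)),))


@pytest.fixture
def small_spec():
    """11 Å cube at 1 Å resolution -> 12 points per axis."""
    return GridSpec(side=11.0, resolution=1.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
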