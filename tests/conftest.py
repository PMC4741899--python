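import numpy as np
import pytest

from hla_tdsm import StructureModel, load_pilot_study


@pytest.fixture(scope="session")
def pilot():
    return load_pilot_study()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_model(coords, numbers=None, allele=None):
    coords = np.asarray(coords, dtype=float)
    if numbers is None:
        numbers = tuple(range(1, len(coords) + 1))
    return StructureModel(allele, tuple(numbers), coords)


@pytest.fixture
def cloud(rng):
    """A well-conditioned random 10-point cloud."""
    return rng.normal(scale=5.0, size=(10, 3))


def random_rigid(rng):
    from scipy.spatial.transform import Rotation

    return Rotation.random(rng=rng).as_matrix(), rng.normal(scale=10.0, size=3)
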