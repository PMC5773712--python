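import numpy as np
import pytest

from sigpep import PropertyTable, SCHEMES
from sigpep.data import SyntheticSpec, generate_synthetic


@pytest.fixture(scope="session")
def tables():
    return PropertyTable.load_default()


@pytest.fixture(scope="session")
def schemes():
    return SCHEMES


@pytest.fixture(scope="session")
def small_dataset():
    """A compact seeded synthetic dataset shared by classifier/evaluation tests."""
    spec = SyntheticSpec(seed=11, n_pos=40, n_neg=40)
    return generate_synthetic(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_sequence(rng, length, alphabet="ACDEFGHIKLMNPQRSTVWY"):
    return "".join(rng.choice(list(alphabet), size=length))
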