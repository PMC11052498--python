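import numpy as np
import pytest

from qsarkit.datasets import load_aurora_predictions, load_aurora_table
from qsarkit.synthetic import generate_random_graphs


@pytest.fixture(scope="session")
def aurora_table():
    return load_aurora_table()

@pytest.fixture(scope="session")
def aurora_predictions():
    return load_aurora_predictions()


@pytest.fixture(scope="session")
def random_mols():
    """120 seed-fixed valence-valid random molecules for property tests."""
    return generate_random_graphs(120, size_range=(3, 10), seed=2024)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
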