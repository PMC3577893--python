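import numpy as np
import pytest

from otulink.distances import DistanceMatrix
from otulink.simulate import simulate_worked_examples


@pytest.fixture(scope="session")
def examples():
    return simulate_worked_examples()


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_distance_matrix(rng, n, scale=0.1):
    """Random symmetric distance matrix with zero diagonal."""
    d = rng.uniform(0, scale, size=(n, n))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    ids = [f"e{i:02d}" for i in range(n)]
    return DistanceMatrix(ids, d)
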