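import numpy as np
import pytest

from vpsearch.datamodel import get_metric
from vpsearch.synthdata import SyntheticSpec, generate

EUCLIDEAN = get_metric("euclidean")


@pytest.fixture(scope="session")
def default_dataset():
    """The default two-cluster fixture shared across suites."""
    matrix, labels = generate(SyntheticSpec())
    return matrix, labels


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_records(rng, n, dim, scale=1.0):
    """n random records keyed r0000..; helper, not a fixture."""
    data = rng.normal(0.0, scale, size=(n, dim))
    return {f"r{i:04d}": data[i] for i in range(n)}
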