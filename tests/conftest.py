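import numpy as np
import pytest

from pathgwas.io_formats import PpiNetwork


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def path5():
    """Path graph A-B-C-D-E."""
    return PpiNetwork.from_edges([("A", "B"), ("B", "C"), ("C", "D"), ("D", "E")])


@pytest.fixture
def triangle():
    return PpiNetwork.from_edges([("A", "B"), ("B", "C"), ("A", "C")])
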