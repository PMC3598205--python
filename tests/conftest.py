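import numpy as np
import pytest

from ddirate.engine import load_default_config
from ddirate.study import load_fixture


@pytest.fixture(scope="session")
def default_config():
    return load_default_config()


@pytest.fixture(scope="session")
def fixture():
    return load_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(20120820)


def random_table(rng, n_max=50, k=5):
    """A random k x k count table with 1..n_max cases."""
    n = int(rng.integers(1, n_max + 1))
    cells = rng.integers(0, k * k, size=n)
    counts = np.bincount(cells, minlength=k * k).reshape(k, k)
    return counts
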