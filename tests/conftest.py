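import numpy as np
import pytest

from bidisperse.lookup import GridSpec, build_table


@pytest.fixture(scope="session")
def small_table():
    """A coarse table covering the mean/dispersion range of the test models."""
    return build_table(GridSpec(0.05, 10.0, 0.05, 0.25, 3.0, 0.25))


@pytest.fixture(scope="session")
def default_table():
    """The full default grid (mu 0.01..32 step 0.01, nu 0..10 step 0.05)."""
    return build_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
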