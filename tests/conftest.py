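import numpy as np
import pandas as pd
import pytest

from riceval import fixtures
from riceval.reproduce import fixture_correlation

REPRESENTATIVES = {
    "palatability", "adhesiveness", "b_value", "resilience", "iodine_color_value",
}


@pytest.fixture(scope="session")
def table2():
    return fixtures.load_fixture("table2")


@pytest.fixture(scope="session")
def panel_correlation():
    """Published 17x17 correlation matrix with printed flags, n = 108."""
    return fixture_correlation()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240101)


@pytest.fixture()
def small_table(rng):
    """A well-behaved 30 x 4 measurement table."""
    cols = ["w", "x", "y", "z"]
    vals = rng.normal(loc=[10, -5, 0.5, 100], scale=[2, 1, 0.1, 20], size=(30, 4))
    return pd.DataFrame(vals, columns=cols,
                        index=[f"s{i}" for i in range(30)])
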