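import numpy as np
import pytest

from pprforge import design_array, unit_table


@pytest.fixture(scope="session")
def rpoa_array():
    """The nine-motif array designed against the rpoA target segment."""
    return design_array("UUACACGUG")


@pytest.fixture(scope="session")
def unit():
    return unit_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
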