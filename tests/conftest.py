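import numpy as np
import pytest

from cosolv.datasets import aspirin_ethanol_water


@pytest.fixture(scope="session")
def aspirin():
    """The packaged ASA / ethanol + water dataset (44 records)."""
    return aspirin_ethanol_water()


@pytest.fixture(scope="session")
def f1_grid():
    return np.round(np.arange(0.0, 1.01, 0.1), 2)
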