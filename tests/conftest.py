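import numpy as np
import pytest

from worklistsim.catalog import default_catalog
from worklistsim.timing import default_histograms


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def histograms():
    """Default synthetic (arrival, reporting) histograms."""
    return default_histograms()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
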