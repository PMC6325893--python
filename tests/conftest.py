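import numpy as np
import pytest
from hypothesis import settings

from sizedist import SizeHistogram

settings.register_profile("repro", deadline=None, derandomize=True)
settings.load_profile("repro")


@pytest.fixture
def simple_hist() -> SizeHistogram:
    return SizeHistogram("S1", bin_values=[10.0, 20.0, 30.0], frequencies=[0.2, 0.3, 0.5])


@pytest.fixture
def gamma_sample():
    """A fixed gamma(6.6, 0.06) sample of 1000 values (wild-type-like sizes)."""
    rng = np.random.default_rng(12345)
    return rng.gamma(6.6, 1.0 / 0.06, 1000)


@pytest.fixture
def small_sample():
    """A fixed 50-point gamma-like sample for oracle comparisons."""
    rng = np.random.default_rng(987)
    return rng.gamma(5.0, 20.0, 50)
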