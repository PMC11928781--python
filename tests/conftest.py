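import numpy as np
import pytest

from compatint import RatioEstimate


@pytest.fixture
def primary():
    """VOYAGER PAD ischemic-cardiovascular-disease estimate."""
    return RatioEstimate("primary", 0.85, 0.76, 0.96)


@pytest.fixture
def bleeding():
    """VOYAGER PAD endovascular-subgroup bleeding estimate."""
    return RatioEstimate("bleeding", 0.86, 0.40, 1.87)


@pytest.fixture
def bleeding_wide():
    """The companion bleeding estimate with the slightly wider interval."""
    return RatioEstimate("bleeding_wide", 0.86, 0.39, 1.91)


@pytest.fixture
def estimate4():
    """Small-but-real harm inside the margins: HR 1.15 (1.06; 1.24)."""
    return RatioEstimate("estimate4", 1.15, 1.06, 1.24)


@pytest.fixture
def rng():
    return np.random.default_rng(20240401)
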