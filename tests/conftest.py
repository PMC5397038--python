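import numpy as np
import pytest

from cellmech import DEFAULT_PROBE, FitConfig, Probe


@pytest.fixture
def probe() -> Probe:
    return DEFAULT_PROBE


@pytest.fixture
def fit_config() -> FitConfig:
    return FitConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
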