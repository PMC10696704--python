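import numpy as np
import pytest

from sipautotroph import RunConfig


@pytest.fixture
def config() -> RunConfig:
    return RunConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)
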