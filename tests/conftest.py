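import numpy as np
import pytest

from tipsplit.core import ModelParams


@pytest.fixture(scope="session")
def wildtype() -> ModelParams:
    return ModelParams()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
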