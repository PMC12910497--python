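import numpy as np
import pytest

from memphys.synthetic import EffectModel


@pytest.fixture(scope="session")
def em() -> EffectModel:
    return EffectModel()


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
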