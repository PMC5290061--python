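import numpy as np
import pytest

from rootwormsim.climate import TemperatureField, N_DEPTHS
from rootwormsim.roots import RootParams
from rootwormsim.rootworm import PestParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def root_params():
    return RootParams()


@pytest.fixture
def pest_params():
    return PestParams()


def constant_field(temp_c: float, hours: int = 48) -> TemperatureField:
    return TemperatureField(np.full((hours, N_DEPTHS), temp_c))
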