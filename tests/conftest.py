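import numpy as np
import pytest

from ffsdoct.config import ObjectiveSpec, SourceSpec


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def led_source():
    return SourceSpec(850.0, 30.0)


@pytest.fixture
def objective():
    return ObjectiveSpec()
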