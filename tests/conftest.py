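import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def default_model():
    from evascore.activity import EvaActivityResults

    return EvaActivityResults.default()
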