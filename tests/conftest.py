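import numpy as np
import pytest

from menisim import build_traditional_matrix


@pytest.fixture
def traditional_matrix():
    return build_traditional_matrix()


@pytest.fixture
def rng():
    return np.random.default_rng(20190510)
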