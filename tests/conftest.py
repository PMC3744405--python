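import numpy as np
import pytest

from sensearch.fixtures import make_fixtures


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def layouts():
    return make_fixtures()
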