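import numpy as np
import pytest

from rheotad.fixture import load_fixture


@pytest.fixture(scope="session")
def fixture_entries():
    return load_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(20120329)
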