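import numpy as np
import pytest

from _util import make_reference


@pytest.fixture(scope="session")
def reference():
    """3 kb random reference on chr1 shared across the suite."""
    return make_reference()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
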