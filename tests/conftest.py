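import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def collection():
    """The packaged 87-entry collection table."""
    from sproutscreen import load_fixture

    return load_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(20170913)
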