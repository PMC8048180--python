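import numpy as np
import pytest

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover - hypothesis is a test extra
    pass

from greykappa import load_fixture, normalize


@pytest.fixture(scope="session")
def original():
    """The 4x4 radiologist worked-example counts table (N = 85)."""
    return load_fixture("original")


@pytest.fixture(scope="session")
def original_p(original):
    return normalize(original)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
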