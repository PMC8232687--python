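import numpy as np
import pytest

from nhejacc.synthetic_data import DEFAULT_TAG, make_synthetic_target
from nhejacc.target_model import GenomeTarget


@pytest.fixture(scope="session")
def tag():
    return DEFAULT_TAG


@pytest.fixture(scope="session")
def toy_target():
    """A deterministic 220-nt '+' strand target for oracle tests."""
    return make_synthetic_target(np.random.default_rng(123), name="toy")


@pytest.fixture(scope="session")
def toy_target_minus():
    return make_synthetic_target(
        np.random.default_rng(321), name="toy_minus", strand="-"
    )


def make_plus_target(rng=None, **kw):
    """Helper used across test modules."""
    rng = rng if rng is not None else np.random.default_rng(0)
    return make_synthetic_target(rng, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
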