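import numpy as np
import pytest
from hypothesis import settings

from tvfc.parcellation import Parcellation

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_parcellation():
    """Six ROIs in three networks (3 + 2 + 1 members)."""
    return Parcellation(
        ("A", "B", "C", "D", "E", "F"),
        ("net1", "net1", "net1", "net2", "net2", "net3"),
    )


@pytest.fixture
def small_series(rng):
    """Correlated 60 x 6 series suitable for short-window tests."""
    base = rng.standard_normal((60, 3))
    mix = rng.standard_normal((3, 6))
    return base @ mix + 0.5 * rng.standard_normal((60, 6))
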