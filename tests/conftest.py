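import numpy as np
import pytest

from comorbnet import make_cohort


@pytest.fixture
def toy6():
    """6 subjects, 3 conditions, unit weights; every pair co-occurs."""
    indicators = np.array([
        [1, 1, 0],
        [1, 1, 1],
        [0, 1, 1],
        [1, 0, 0],
        [0, 0, 1],
        [1, 1, 0],
    ])
    return make_cohort(indicators, ["a", "b", "c"])


@pytest.fixture
def toy12():
    """12 subjects, 4 conditions, heterogeneous weights."""
    rng = np.random.default_rng(7)
    indicators = rng.integers(0, 2, size=(12, 4))
    # force one fully comorbid subject so at least one triad exists
    indicators[0] = 1
    weights = rng.uniform(0.5, 1.8, size=12)
    return make_cohort(indicators, ["a", "b", "c", "d"], weights=weights)
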