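import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from iimtseg import GrayHistogram


def random_histogram(rng: np.random.Generator, n_occupied: int,
                     span: int = 256) -> GrayHistogram:
    """Histogram with ``n_occupied`` occupied bins at random positions.

    Masses are strictly positive continuous random values, so threshold
    optima are generically unique.
    """
    lo = int(rng.integers(0, 256 - span + 1)) if span < 256 else 0
    positions = rng.choice(np.arange(lo, lo + span), size=n_occupied, replace=False)
    p = np.zeros(256)
    p[positions] = rng.uniform(0.1, 1.0, size=n_occupied)
    return GrayHistogram.from_probabilities(p)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def uniform_hist():
    return GrayHistogram.from_probabilities(np.full(256, 1 / 256))


@pytest.fixture
def two_spike_hist():
    p = np.zeros(256)
    p[0] = p[255] = 0.5
    return GrayHistogram.from_probabilities(p)
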