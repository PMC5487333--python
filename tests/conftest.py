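import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from malsf import majority_vote, segment, standard_fixture


@pytest.fixture(scope="session")
def standard():
    """The standard desk-scale fixture (seed 0)."""
    return standard_fixture(0)


@pytest.fixture(scope="session")
def standard_segmentation(standard):
    """Default-parameter segmentation of the standard fixture, plus the
    majority-vote baseline (shared across tests; fully deterministic)."""
    img, truth, ensemble = standard
    result = segment(img, ensemble)
    mv = majority_vote(ensemble.labels)
    return result, mv


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_mask(rng, shape, p=0.4, nonempty=True):
    """A random binary mask, guaranteed non-degenerate when requested."""
    while True:
        m = (rng.random(shape) < p).astype(np.uint8)
        if not nonempty or (m.any() and not m.all()):
            return m
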