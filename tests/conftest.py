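import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def two_square_clusters():
    """Two 2-point clusters: radii 1, centroid distance 10."""
    points = np.array([[0.0, 0.0], [0.0, 2.0], [10.0, 0.0], [10.0, 2.0]])
    labels = np.array([0, 0, 1, 1])
    return points, labels


@pytest.fixture
def four_point_line():
    """1-D points {0, 0.1, 10, 10.1} with the natural 2-clustering."""
    points = np.array([[0.0], [0.1], [10.0], [10.1]])
    labels = np.array([0, 0, 1, 1])
    return points, labels


def random_mask(rng, shape=(64, 64), density=0.45):
    return rng.random(shape) < density
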