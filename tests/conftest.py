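import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from lgcw.core import EnergyParams, Image2D, LevelSetState, gaussian_kernel


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_kernel():
    return gaussian_kernel(1.5, 3)


def random_state(rng, shape=(8, 8), centers=(120.0, 40.0)):
    """A random-but-valid level-set state on a small grid."""
    return LevelSetState(
        phi=rng.normal(0, 3, shape),
        epsilon=1.0,
        bias=rng.uniform(0.7, 1.3, shape),
        centers=centers,
    )


def random_image(rng, shape=(8, 8)):
    return Image2D(rng.uniform(0, 255, shape))
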