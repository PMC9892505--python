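import numpy as np
import pytest

from audioshape.core import Audiogram, FrequencyGrid
from audioshape.synth import bisgaard_like_archetypes, make_dataset, make_reference_set

# the sloping audiogram used as a worked example throughout: range exactly 60 dB
WORKED_LEVELS = [10.0, 20.0, 35.0, 35.0, 40.0, 45.0, 50.0, 70.0]


@pytest.fixture(scope="session")
def grid():
    return FrequencyGrid()


@pytest.fixture(scope="session")
def refs():
    return make_reference_set()


@pytest.fixture()
def worked_audiogram(grid):
    return Audiogram(levels=np.array(WORKED_LEVELS), id="worked", grid=grid)


@pytest.fixture(scope="session")
def loss_dataset():
    """60 hearing-loss audiograms: 10 shape families x 6 noisy samples."""
    return make_dataset(bisgaard_like_archetypes(include_normal=False), seed=0)


@pytest.fixture(scope="session")
def full_dataset():
    """66 audiograms including the normal-hearing family."""
    return make_dataset(bisgaard_like_archetypes(include_normal=True), seed=0)


def random_audiograms(n, rng, grid=None, lo=25.0, hi=110.0):
    """Non-constant random audiograms with strictly positive levels."""
    grid = grid or FrequencyGrid()
    out = []
    for i in range(n):
        levels = rng.uniform(lo, hi, size=8)
        while np.ptp(levels) == 0:  # pragma: no cover - probability zero
            levels = rng.uniform(lo, hi, size=8)
        out.append(Audiogram(levels=levels, id=f"r{i}", grid=grid))
    return out
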