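import numpy as np
import pytest

from motilitykit.scratch import StructureMap
from motilitykit.synthetic import ScratchSimParams, TrackSimParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_scratch_params():
    """A small, fast well: 300x150 px, 100 px scratch, 10 px/h closure."""
    return ScratchSimParams(
        image_width=300,
        image_height=150,
        initial_scratch_width=100,
        closure_rate=10.0,
        n_frames=9,
        seed=7,
    )


@pytest.fixture
def default_track_params():
    return TrackSimParams(seed=11)


def make_structure_map(values):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    return StructureMap(values=values, window=50, stride=5)
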