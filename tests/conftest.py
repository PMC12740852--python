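import numpy as np
import pytest

from saligaze.fixations import Fixation, GazeRecording
from saligaze.salience import SaliencyMap


@pytest.fixture
def small_map():
    """One-blob map with its peak pinned at the grid center."""
    from saligaze.synth import make_saliency_map

    return make_saliency_map(11, image_size=(200, 150), n_blobs=1,
                             centers=[(100, 75)])


@pytest.fixture
def multi_blob_map():
    from saligaze.synth import make_saliency_map

    return make_saliency_map(42, image_size=(320, 240), n_blobs=4)


def make_recording(positions, rate=150.0, screen=(800, 600), valid=None):
    """Recording that dwells at each (x, y, n_samples) position in turn."""
    xs, ys = [], []
    for x, y, n in positions:
        xs.extend([x] * n)
        ys.extend([y] * n)
    n_tot = len(xs)
    if valid is None:
        valid = np.ones(n_tot, dtype=bool)
    return GazeRecording(t=np.arange(n_tot) / rate, x=np.array(xs, float),
                         y=np.array(ys, float), valid=valid, rate=rate,
                         screen=screen)


def fix(x, y, onset=0.0, duration=0.2):
    return Fixation(x=x, y=y, onset=onset, duration=duration)
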