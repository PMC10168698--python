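import numpy as np
import pytest

from walkmap.preprocess import PreprocessParams, VolumeSeries
from walkmap.synth import BehaviorTrace


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def params():
    return PreprocessParams()


def behavior_from_labels(labels, frame_rate_hz=1.0, speed_when_walk=5.0):
    """Build a BehaviorTrace straight from a label sequence."""
    labels = np.asarray(labels, dtype=object)
    fwd = np.where(labels == "walk", speed_when_walk, 0.0)
    zeros = np.zeros(len(labels))
    return BehaviorTrace(fwd, zeros, zeros, labels, frame_rate_hz)


def movie_from_array(data, frame_rate_hz=10.0, space="raw"):
    return VolumeSeries(np.asarray(data, dtype=np.float64), frame_rate_hz, space=space)
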