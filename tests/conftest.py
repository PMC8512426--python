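import numpy as np
import pytest
from hypothesis import settings

from glovescan.geometry import ObjectFramePoint, ReferencePoint

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def origin_ref():
    return ReferencePoint(id=0, position=np.zeros(3))


def make_points(positions, times=None, sensor_ids=None):
    """Build ObjectFramePoint lists from raw arrays for filter tests."""
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    n = len(positions)
    times = np.zeros(n) if times is None else np.asarray(times, dtype=float)
    sensor_ids = np.ones(n, dtype=int) if sensor_ids is None else np.asarray(sensor_ids)
    return [
        ObjectFramePoint(positions[i], int(sensor_ids[i]), float(times[i]))
        for i in range(n)
    ]
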