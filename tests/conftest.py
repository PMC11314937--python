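import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cricketcount import DetectionRecord, InfoMatrix

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_matrix(rows, n_frames=None, fps=5.0, width=1920.0, height=1080.0):
    """Build an InfoMatrix from (frame, layer, cls, prob, cx, cy) tuples."""
    records = {}
    for frame, layer, cls, prob, cx, cy in rows:
        records[(frame, layer)] = DetectionRecord(frame, layer, cls, prob, cx, cy)
    if n_frames is None:
        n_frames = max((f for f, _, *_ in rows), default=-1) + 1
    return InfoMatrix(
        n_frames=n_frames,
        fps=fps,
        frame_width=width,
        frame_height=height,
        records=records,
    )


@pytest.fixture
def single_track_matrix():
    """One cricket walking right at 10 px/frame for 20 frames."""
    rows = [
        (f, 1, 0, 0.9, 100.0 + 10.0 * f, 500.0) for f in range(20)
    ]
    return make_matrix(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
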