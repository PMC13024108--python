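import numpy as np
import pytest

from kinemark import Landmark2D, PoseFrame, PoseSequence


def make_frame(t: float, pts: dict[str, tuple[float, float]], visibility: float = 1.0) -> PoseFrame:
    """Frame from {name: (x, y)} with a common visibility."""
    return PoseFrame(
        timestamp=t,
        landmarks={
            n: Landmark2D(x=x, y=y, visibility=visibility) for n, (x, y) in pts.items()
        },
    )


def make_sequence(frames, **kwargs) -> PoseSequence:
    return PoseSequence(frames=frames, **kwargs)


@pytest.fixture
def static_left_leg():
    """50 identical frames of a bent left leg at 20 Hz, all landmarks visible."""
    pts = {
        "LEFT_HIP": (0.5, 0.3),
        "LEFT_KNEE": (0.5, 0.5),
        "LEFT_ANKLE": (0.65, 0.55),
        "LEFT_FOOT_INDEX": (0.7, 0.6),
    }
    frames = [make_frame(i * 0.05, pts) for i in range(50)]
    return make_sequence(frames)


@pytest.fixture
def rng():
    return np.random.default_rng(20261001)
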