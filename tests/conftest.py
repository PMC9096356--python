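import numpy as np
import pytest

from vitalcam.geometry import BoundingBox, FaceDetection


@pytest.fixture
def detection():
    """A typical frontal detection: 100x120 box at (10, 20), eyes at y=60."""
    return FaceDetection(box=BoundingBox(10, 20, 100, 120), y_eye=60)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
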