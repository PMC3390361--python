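import numpy as np
import pytest

from whiskertrack.detector_bank import DetectorBank
from whiskertrack.imgproc import Frame


@pytest.fixture(scope="session")
def bank():
    """One shared lazily-built detector bank for the whole session."""
    return DetectorBank()


def make_line_frame(
    angle_deg: float,
    width: float = 2.0,
    center=(50.0, 50.0),
    shape=(100, 100),
    background: float = 200.0,
    core: float = 40.0,
    noise: float = 0.0,
    seed: int = 0,
) -> Frame:
    """Infinite straight dark line with exact 1-D anti-aliasing."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    theta = np.radians(angle_deg)
    # signed distance to the line through `center` at angle
    d = np.abs(
        -np.sin(theta) * (xx - center[0]) + np.cos(theta) * (yy - center[1])
    )
    ov = np.clip(np.minimum(width / 2, d + 0.5) - np.maximum(-width / 2, d - 0.5), 0, 1)
    img = background - ov * (background - core)
    if noise > 0:
        img = img + np.random.default_rng(seed).normal(0, noise, img.shape)
    return Frame(np.clip(img, 0, 255))


@pytest.fixture
def line_frame():
    return make_line_frame(0.0)
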