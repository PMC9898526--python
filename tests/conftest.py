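import numpy as np
import pytest

from foldflow import FoldFront, SyntheticStudyConfig, run_pipeline


@pytest.fixture(scope="session")
def default_study_result():
    """The reference synthetic study analysed end-to-end (shared: it is the
    most expensive fixture in the suite)."""
    config = SyntheticStudyConfig()
    return config, run_pipeline(config)


@pytest.fixture()
def quarter_circle():
    """Quarter circle of radius 100 µm sampled every 5 degrees, curvature
    center on the +z side."""
    theta = np.deg2rad(np.arange(0.0, 90.1, 5.0))
    pts = np.stack([100.0 * np.sin(theta), 100.0 * (1.0 - np.cos(theta))], axis=1)
    return FoldFront(time=0.0, points=pts)


def circle_front(r=100.0, n=200, time=0.0):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = np.stack([r * np.cos(th), r * np.sin(th)], axis=1)
    return FoldFront(time=time, points=pts, closed=True)
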