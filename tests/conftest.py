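import numpy as np
import pytest

from contourpose.hough_ellipse import DetectionParams
from contourpose.synthetic import make_crawler


@pytest.fixture(scope="session")
def crawler_scene():
    """High-contrast single-crawler scene (60 frames) with ground truth."""
    return make_crawler(T=60, seed=1)


@pytest.fixture(scope="session")
def crawler_params():
    return DetectionParams(min_major=40, max_major=80, n_animals=1)


def ellipse_edge_points(a=40, b=20, theta_deg=30.0, center=(100.0, 100.0),
                        shape=(200, 200)):
    """Rasterised boundary of an ellipse, as (x, y) points (oracle input)."""
    from skimage.draw import ellipse_perimeter
    rr, cc = ellipse_perimeter(int(center[1]), int(center[0]), int(b), int(a),
                               orientation=np.deg2rad(theta_deg), shape=shape)
    return np.column_stack([cc, rr]).astype(float)


@pytest.fixture(scope="session")
def canonical_ellipse_edges():
    return ellipse_edge_points()
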