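import numpy as np
import pytest

from flashtrace.imaging import preprocess
from flashtrace.render import RenderConfig, render_stack
from flashtrace.trajectory import FiberTrace


@pytest.fixture(scope="session")
def straight_fiber_stack():
    """A 40 x 20 x 6 um stack with one straight fiber along x at mid-depth.

    Returned preprocessed, together with the ground-truth endpoints and the
    calibration, for tracer tests that need a clean, known geometry.
    """
    pts = np.array([[2.0, 10.0, 3.0], [38.0, 10.0, 3.0]])
    cfg = RenderConfig(noise_sd=0.05, seed=1)
    stack = render_stack([pts], (40.0, 20.0, 6.0), (0.06, 0.3), cfg)
    return preprocess(stack), pts, cfg


@pytest.fixture(scope="session")
def gap_fiber_stack():
    """The same straight fiber with a single 2 um signal gap."""
    pts = np.array([[2.0, 10.0, 3.0], [38.0, 10.0, 3.0]])
    cfg = RenderConfig(noise_sd=0.05, seed=1)
    stack = render_stack([pts], (40.0, 20.0, 6.0), (0.06, 0.3), cfg,
                         forced_gaps=[[(20.0, 22.0)]])
    return preprocess(stack), pts


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_polyline(rng, n_points=20, scale=2.0):
    steps = rng.normal(0.0, scale, size=(n_points - 1, 3))
    pts = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
    return FiberTrace(pts)
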