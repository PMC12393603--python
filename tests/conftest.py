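import numpy as np
import pytest

from caliper.phantom import PhantomSpec, make_wedge_slice


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def wedge100():
    """Noiseless 100-degree wedge slice, mask, and analytic truth (seed 0)."""
    spec = PhantomSpec(apex_angle_deg=100.0, noise_sd=0.0)
    sl, mask, truth = make_wedge_slice(spec)
    return spec, sl, mask, truth


def rectangle_polygon(x0, x1, y0, y1, n_per_edge=20):
    """Dense boundary polygon of an axis-aligned rectangle (ccw)."""
    xs = np.linspace(x0, x1, n_per_edge, endpoint=False)
    ys = np.linspace(y0, y1, n_per_edge, endpoint=False)
    top = np.stack([xs, np.full_like(xs, y0)], axis=1)
    right = np.stack([np.full_like(ys, x1), ys], axis=1)
    bottom = np.stack(
        [np.linspace(x1, x0, n_per_edge, endpoint=False), np.full_like(xs, y1)], axis=1
    )
    left = np.stack(
        [np.full_like(ys, x0), np.linspace(y1, y0, n_per_edge, endpoint=False)], axis=1
    )
    return np.concatenate([top, right, bottom, left], axis=0)
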