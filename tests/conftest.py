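import numpy as np
import pytest

from lfmkit.simulate import SimConfig, simulate_timelapse


@pytest.fixture(scope="session")
def small_field():
    """A 20-cell noisy field with deaths, shared across imaging tests."""
    cfg = SimConfig(n_cells=20, field_size=220, seed=42)
    stack, truth = simulate_timelapse(cfg)
    return cfg, stack, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def make_blob_frame(shape, centers, amplitude=100.0, sigma=3.0, background=0.0):
    """Sum of isotropic Gaussian blobs; shared helper for imaging tests."""
    img = np.full(shape, float(background))
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for (x, y) in centers:
        img += amplitude * np.exp(
            -((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma**2)
        )
    return img
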