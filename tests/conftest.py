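import numpy as np
import pytest

from afmkalman import ConeSpec, GridGeometry, WalkConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def tiny_geometry():
    return GridGeometry(3, 3)


@pytest.fixture
def tiny_walk_config(tiny_geometry):
    """Small deterministic twin-experiment fixture: 3x3 grid, 5 frames."""
    return WalkConfig(
        geometry=tiny_geometry,
        cone=ConeSpec(base_radius=1.5, height=3.0),
        n_ticks=45,
        scale=0.1,
        noise_sd=0.3,
        seed=7,
    )


def random_psd(rng, k, jitter=0.1):
    a = rng.normal(size=(k, k))
    return a @ a.T + jitter * np.eye(k)
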