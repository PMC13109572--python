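import numpy as np
import pytest

from voxfpar.cloud import PointCloud
from voxfpar.synthetic import StandConfig, generate_stand


@pytest.fixture
def small_config():
    """A 12-tree stand small enough for fast end-to-end chains."""
    return StandConfig(n_rows=3, n_cols=4, n_families=4, seed=11)


@pytest.fixture
def small_scene(small_config):
    return generate_stand(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(7)


def random_cloud(rng, n=1000, extent=20.0, zmax=25.0, classified=False):
    cls = None
    if classified:
        cls = rng.choice([1, 2, 5], size=n).astype(np.uint8)
    return PointCloud(
        rng.uniform(0, extent, n),
        rng.uniform(0, extent, n),
        rng.uniform(0, zmax, n),
        cls,
    )
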