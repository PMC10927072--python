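import numpy as np
import pytest

from scgeom.geodesic import DiffusionConfig
from scgeom.metrics import ScoreConfigs
from scgeom.preprocess import PointCloud
from scgeom.simulate import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_diffusion():
    """Neighborhood small enough for clouds of a few dozen points."""
    return DiffusionConfig(n_graph_neighbors=6, n_diffusion_components=5)


@pytest.fixture
def small_configs(small_diffusion):
    return ScoreConfigs(diffusion=small_diffusion)


@pytest.fixture
def small_sim_config():
    """Smaller clouds for unit tests; structure and defaults otherwise intact."""
    return SimConfig(n_points_range=(60, 140))


def blob_cloud(rng, n=60, d=2, scale=1.0):
    return PointCloud(coords=scale * rng.normal(size=(n, d)))


def clusters_cloud(rng, centers, n_per=25, sigma=0.15):
    parts = [np.asarray(c) + sigma * rng.normal(size=(n_per, len(c))) for c in centers]
    return PointCloud(coords=np.concatenate(parts, axis=0))


def segment_cloud(rng, n=200, noise=0.01):
    t = rng.uniform(0, 1, n)
    return PointCloud(coords=np.column_stack([t, noise * rng.normal(size=n)]))
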