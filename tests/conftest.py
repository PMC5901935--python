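import numpy as np
import pytest

from voxelfc.core import BoldSeries
from voxelfc.synthetic import SimConfig, make_brain_mask, make_network_templates

GRID = (18, 18, 12)


def make_series(data: np.ndarray, tr: float = 2.5) -> BoldSeries:
    """Wrap a (n_voxels, T) matrix in a BoldSeries on a minimal line mask."""
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    mask = np.zeros((n, 1, 1), dtype=bool)
    mask[:, 0, 0] = True
    coords = np.array([[i, 0, 0] for i in range(n)])
    return BoldSeries(data=data, tr=tr, mask=mask,
                      affine=np.diag([3.0, 3.0, 3.0, 1.0]),
                      voxel_coords=coords)


@pytest.fixture(scope="session")
def grid():
    return GRID


@pytest.fixture(scope="session")
def brain_mask():
    return make_brain_mask(GRID)


@pytest.fixture(scope="session")
def templates():
    return make_network_templates(GRID)


@pytest.fixture(scope="session")
def templates_by_name(templates):
    return {t.name: t for t in templates}


@pytest.fixture
def sim_config():
    return SimConfig(rng_seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
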