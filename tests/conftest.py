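import numpy as np
import pandas as pd
import pytest

from neurocoloc.synthetic import SyntheticSpec, make_atlas, make_template_maps
from neurocoloc.types import LabelAtlas


@pytest.fixture(scope="session")
def spec40() -> SyntheticSpec:
    """Desk-scale study conditions: 12^3 grid, 40 regions, 20 per group."""
    return SyntheticSpec(seed=7)


@pytest.fixture(scope="session")
def atlas40(spec40):
    return make_atlas(spec40)


@pytest.fixture(scope="session")
def templates16(atlas40):
    return make_template_maps(atlas40, 16, seed=7)


@pytest.fixture(scope="session")
def atlas119():
    """119-region atlas on a 24^3 grid (region count of the reference atlas)."""
    return make_atlas(SyntheticSpec(grid_shape=(24, 24, 24), n_regions=119, seed=11))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


@pytest.fixture()
def toy_atlas() -> LabelAtlas:
    """5-voxel, 2-region atlas on a 5x1x1 grid for hand computations."""
    labels = np.array([1, 2, 1, 2, 2], dtype=np.int32).reshape(5, 1, 1)
    regions = pd.DataFrame(
        dict(id=[1, 2], name=["r1", "r2"], x=[1.0, 8.0 / 3], y=[0.0, 0.0], z=[0.0, 0.0])
    )
    return LabelAtlas(labels=labels, affine=np.eye(4), regions=regions)
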