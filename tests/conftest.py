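import numpy as np
import pytest

import focimeta as fm


@pytest.fixture(scope="session")
def brand_table():
    """Bundled 26x2 cluster-by-condition counts (679 vs 733 foci)."""
    return fm.load_brand_contingency()


@pytest.fixture(scope="session")
def brand_contrast(brand_table):
    return fm.ClusterContrast().fit_table(brand_table)


@pytest.fixture(scope="session")
def retained_table(brand_table, brand_contrast):
    return brand_table.drop(index=brand_contrast.roles("overlapped"))


@pytest.fixture(scope="session")
def coarse_grid():
    """4 mm ellipsoid-masked grid used by the heavier spatial tests."""
    return fm.default_grid(voxel_size=4.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
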