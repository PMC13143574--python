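import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cloud(rng):
    """1000 uniform points in a 10 m cube."""
    from canopy_complexity.io import PointCloud

    return PointCloud(rng.uniform(0, 10, size=(1000, 3)), source_id="small")
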