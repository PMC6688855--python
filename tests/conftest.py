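import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from marshcover.geometry import default_design
from marshcover.raster import BARREN, NONSHRUB, SHRUB, ClassRaster
from marshcover.synthetic import SceneSpec, generate_truth_map


@pytest.fixture(scope="session")
def tiny_design():
    """Two plots, 8 cells of 50 x 50 m (2 rows x 2 cols each)."""
    return default_design(plot_cell_counts=(4, 4), plot_rows=2, scaled=True)


@pytest.fixture(scope="session")
def tiny_truth(tiny_design):
    """Truth raster over the tiny design at 25 cm GSD (patchy, seeded)."""
    spec = SceneSpec(seed=42, gsd_m=0.25, spatial_corr_length_m=4.0)
    return generate_truth_map(spec, tiny_design.extent_m)


def uniform_raster(label: int, shape=(40, 40), gsd_m=0.5) -> ClassRaster:
    return ClassRaster(np.full(shape, label, dtype=np.uint8), gsd_m=gsd_m)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
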