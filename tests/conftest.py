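import numpy as np
import pytest

from autoplan.grid import Grid, RoiMask
from autoplan.phantom import PhantomConfig, generate_case
from autoplan.pipeline import RunConfig, run_pipeline


def make_grid(shape=(20, 20, 20), spacing=1.0, origin=None):
    if origin is None:
        origin = tuple(-(n * spacing) / 2 + spacing / 2 for n in shape)
    return Grid(shape=shape, spacing_mm=(spacing,) * 3, origin_mm=origin)


def sphere_mask(grid: Grid, center_mm, radius_mm, name="sphere") -> RoiMask:
    x, y, z = grid.coord_grids_mm()
    vox = ((x - center_mm[0]) ** 2 + (y - center_mm[1]) ** 2
           + (z - center_mm[2]) ** 2) <= radius_mm ** 2
    return RoiMask(name, grid, vox)


@pytest.fixture(scope="session")
def coarse_config():
    """Default cohort statistics on a 5 mm grid — fast to generate; volumes
    and overlaps are resolution-independent."""
    return PhantomConfig(spacing_mm=5.0, seed=42)


@pytest.fixture(scope="session")
def coarse_case(coarse_config):
    return generate_case(coarse_config)


@pytest.fixture(scope="session")
def default_case():
    """One phantom at the default 2.5 mm grid."""
    return generate_case(PhantomConfig(seed=7))


@pytest.fixture(scope="session")
def default_run():
    """Full pipeline at default settings (2.5 mm phantom grid, 3 mm dose grid,
    36 angles, two rounds x 100 iterations).  Shared across the end-to-end
    and acceptance tests; takes a few minutes."""
    return run_pipeline(RunConfig(seed=0))
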