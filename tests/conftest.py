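import warnings

import pytest

from nucleomech import (
    CellGeometry,
    MaterialParams,
    SweepConfig,
    build_cell_mesh,
    run_sweep,
)

COARSE_RESOLUTION = 2.2


@pytest.fixture(scope="session")
def default_geometry() -> CellGeometry:
    return CellGeometry()


@pytest.fixture(scope="session")
def coarse_mesh(default_geometry):
    return build_cell_mesh(default_geometry, COARSE_RESOLUTION)


@pytest.fixture(scope="session")
def materials() -> MaterialParams:
    return MaterialParams()


@pytest.fixture(scope="session")
def default_sweep_result():
    """The full default Monte-Carlo experiment (5 stiffnesses x 20 replicates)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_sweep(SweepConfig(replicates=20))
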