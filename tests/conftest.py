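import numpy as np
import pytest

from tumorhab.kinetics import AIFModel
from tumorhab.synth import (AcquisitionGrid, default_table,
                            generate_habitat_geometry, mda_mb_231_table,
                            sample_parameter_fields)


@pytest.fixture(scope="session")
def table():
    return default_table()


@pytest.fixture(scope="session")
def mda_table():
    return mda_mb_231_table()


@pytest.fixture(scope="session")
def grid():
    return AcquisitionGrid()


@pytest.fixture(scope="session")
def aif(grid):
    return AIFModel(arrival_s=grid.precontrast_s)


@pytest.fixture(scope="session")
def small_geometry():
    return generate_habitat_geometry(shape=(24, 24, 8), seed=11)


@pytest.fixture(scope="session")
def truth_maps(small_geometry, table):
    return sample_parameter_fields(small_geometry, table, seed=12)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
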