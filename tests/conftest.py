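import numpy as np
import pytest

from tractshift.core import AcquisitionScheme, Grid, default_scheme
from tractshift.experiments import sim_config, sim_tracking_params
from tractshift.phantom import PhantomConfig, make_subject_pair


@pytest.fixture(scope="session")
def default_pair():
    """One full-size synthetic patient (all six bundles, both timepoints)."""
    return make_subject_pair(PhantomConfig(), seed=42)


@pytest.fixture(scope="session")
def small_pair():
    """Scaled-down two-tract subject used by the faster pipeline tests."""
    return make_subject_pair(sim_config(), seed=7)


@pytest.fixture(scope="session")
def scheme() -> AcquisitionScheme:
    return default_scheme()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def small_grid() -> Grid:
    return Grid((10, 10, 10), 2.0)
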