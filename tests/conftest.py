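import numpy as np
import pytest
from hypothesis import strategies as st

from jawsearch.dvh_core import DVHCurve
from jawsearch.jaw_grid import BEVExtent
from jawsearch.pipeline import SearchConfig, run_search

DEFAULT_EXTENT = BEVExtent(-60.0, 60.0, -70.0, 70.0)


@pytest.fixture(scope="session")
def extent() -> BEVExtent:
    return DEFAULT_EXTENT


@pytest.fixture(scope="session")
def default_config() -> SearchConfig:
    return SearchConfig(seed=1)


@pytest.fixture(scope="session")
def search_result(default_config, extent):
    """One full seeded 100-plan search, shared across tests."""
    return run_search(default_config, extent)


@pytest.fixture(scope="session")
def noise_free_config() -> SearchConfig:
    cfg = SearchConfig(seed=1)
    return cfg.model_copy(update={"surrogate": cfg.surrogate.model_copy(update={"noise_sd_gy": 0.0})})


@pytest.fixture(scope="session")
def noise_free_result(noise_free_config, extent):
    return run_search(noise_free_config, extent)


@st.composite
def dvh_curves(draw, max_points: int = 12, max_dose: float = 60.0):
    """Random valid cumulative DVH curves (monotone grids, V(0)=100)."""
    n = draw(st.integers(min_value=2, max_value=max_points))
    steps = draw(
        st.lists(st.floats(0.5, max_dose / max_points), min_size=n - 1, max_size=n - 1)
    )
    dose = np.concatenate([[0.0], np.cumsum(steps)])
    drops = draw(st.lists(st.floats(0.0, 40.0), min_size=n - 1, max_size=n - 1))
    vol = 100.0 - np.concatenate([[0.0], np.cumsum(drops)])
    vol = np.clip(vol, 0.0, 100.0)
    return DVHCurve("random", dose, vol)
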