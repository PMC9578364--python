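import numpy as np
import pytest

from bymmap import SyntheticConfig, build_adjacency, simulate_study
from bymmap.standardize import METHODS


def null_config(**kw) -> SyntheticConfig:
    """Generator config with no covariate effects and no random effects."""
    kw.setdefault("true_beta", {m: {} for m in METHODS})
    kw.setdefault("true_sigma_u", 0.0)
    kw.setdefault("true_sigma_v", 0.0)
    return SyntheticConfig(**kw)


@pytest.fixture(scope="session")
def small_study():
    """An 8x8-lattice study with the default (paper-pattern) truth."""
    cfg = SyntheticConfig(n_areas=64, grid_rows=8, grid_cols=8, seed=5)
    area_frame, geoms, truth = simulate_study(cfg)
    graph = build_adjacency(geoms)
    return area_frame, geoms, truth, graph


@pytest.fixture(scope="session")
def default_study():
    """The full 432-area default study."""
    cfg = SyntheticConfig(seed=11)
    area_frame, geoms, truth = simulate_study(cfg)
    graph = build_adjacency(geoms)
    return area_frame, geoms, truth, graph


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
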