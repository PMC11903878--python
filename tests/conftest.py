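import numpy as np
import pandas as pd
import pytest

from turcmap.spatial import classify_pools
from turcmap.synth import (
    SimulationConfig,
    simulate_centriole,
    simulate_lumenal_turcs,
    simulate_minflux_structures,
    simulate_pericentriolar_turcs,
)


@pytest.fixture(scope="session")
def config():
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def centriole(config):
    return simulate_centriole(config)


@pytest.fixture(scope="session")
def particles(config, centriole):
    lum = simulate_lumenal_turcs(centriole, config)
    peri = simulate_pericentriolar_turcs(centriole, config)
    return pd.concat([lum, peri], ignore_index=True)


@pytest.fixture(scope="session")
def labeled(particles, centriole):
    return classify_pools(particles, centriole)


@pytest.fixture(scope="session")
def minflux_sim():
    cfg = SimulationConfig(seed=3)
    table, truth = simulate_minflux_structures(cfg, return_truth=True)
    return cfg, table, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
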