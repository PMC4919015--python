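import numpy as np
import pytest

from seagrass_metals import SimulationConfig
from seagrass_metals.mixing import MCMCConfig, SourceSummary


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def default_config():
    return SimulationConfig(seed=42)


@pytest.fixture
def informative_sources():
    """Well-separated two-tracer sources: mixing fraction clearly identified."""
    eel = SourceSummary(
        "eelgrass",
        means={"c_content": 35.0, "d13c": -13.4},
        sds={"c_content": 1.5, "d13c": 2.1},
        n=5,
    )
    epi = SourceSummary(
        "epiphytes",
        means={"c_content": 20.0, "d13c": -9.7},
        sds={"c_content": 1.5, "d13c": 0.5},
        n=10,
    )
    return eel, epi


@pytest.fixture
def fast_wre_schedule():
    """Reduced but honest Metropolis schedule for multi-repetition tests."""
    return MCMCConfig(iterations=12_000, burn_in=2_000, thinning=1, seed=0)


@pytest.fixture
def fast_decomp_schedule():
    """Reduced 3-chain Gibbs schedule for multi-repetition tests."""
    return MCMCConfig(iterations=3_000, burn_in=500, thinning=3, chains=3, seed=0)
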