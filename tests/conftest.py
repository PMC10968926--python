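import numpy as np
import pytest

from spatial_ultimatum import (
    GameParams,
    Scenario,
    run_scenario,
    strategy_table,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def strategies():
    return strategy_table()


@pytest.fixture(scope="session")
def baseline_summary():
    """Full-scale baseline: 10 replicates at n=50, D=100, L=1, f=1/2, m=1,
    T=100.  Shared across tests that compare against the reference tables."""
    return run_scenario(Scenario(GameParams(), replicates=10), master_seed=2024)
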