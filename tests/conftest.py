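import numpy as np
import pytest

from connodiff.simulate import SimulationConfig, planted_scenario, simulate_cohort


@pytest.fixture(scope="session")
def null_cohort():
    """A small null cohort (no planted effects, independent parcels)."""
    cfg = SimulationConfig(
        n_parcels=30,
        n_group_a=15,
        n_group_b=15,
        within_block_r=0.0,
        between_block_r=0.0,
        seed=11,
    )
    cohort, truth = simulate_cohort(cfg)
    return cohort


@pytest.fixture(scope="session")
def planted_cohort():
    """Planted-effect cohort shared by recovery tests (strong effects)."""
    cfg = planted_scenario(n_parcels=40, n_group_a=20, n_group_b=20, seed=3)
    return simulate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
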