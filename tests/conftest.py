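import numpy as np
import pytest

from triomr import ScenarioConfig, simulate_trio_cohort


@pytest.fixture(scope="session")
def small_config():
    """A cheap panel for unit tests: 8 variants, 4000 trios."""
    return ScenarioConfig(
        n_trios=4000,
        n_replicates=10,
        n_variants=8,
        q_x=0.02,
        gamma=0.1,
        v_o=0.05,
        v_p=0.01,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_trio_cohort(small_config, 0)


@pytest.fixture(scope="session")
def null_cohort():
    """All genetic and causal paths null."""
    cfg = ScenarioConfig(
        n_trios=5000, n_variants=5, q_x=0.0, gamma=0.0, v_o=0.0, v_p=0.0, seed=3
    )
    return simulate_trio_cohort(cfg, 0)


@pytest.fixture(scope="session")
def big_cohort():
    """One larger cohort shared by correlation-structure tests."""
    cfg = ScenarioConfig(
        n_trios=60000, n_variants=20, q_x=0.02, gamma=0.1, v_o=0.02, v_p=0.01, seed=11
    )
    return simulate_trio_cohort(cfg, 0)


def mc_tolerance(sd: float, n: int, k: float = 3.0) -> float:
    return k * sd / np.sqrt(n)
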