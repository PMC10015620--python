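import numpy as np
import pytest

from poolgea.simulate import (
    SimulationConfig,
    simulate_environment,
    simulate_frequencies,
    simulate_pool_reads,
    simulate_visitation,
)


@pytest.fixture(scope="session")
def small_identity_sim():
    """5k SNPs, identity omega, interior frequencies: cheap shared fixture."""
    cfg = SimulationConfig(
        n_snps=5_000, n_scaffolds=5, omega_spec="identity", pi_range=(0.2, 0.8), seed=7
    )
    freqs, truth = simulate_frequencies(cfg)
    return cfg, freqs, truth


@pytest.fixture(scope="session")
def small_counts(small_identity_sim):
    _, freqs, _ = small_identity_sim
    return simulate_pool_reads(freqs, depth_mean=60, seed=8)


@pytest.fixture(scope="session")
def env_table():
    return simulate_environment(21, seed=5)


@pytest.fixture(scope="session")
def visitation():
    visits, plant = simulate_visitation(21, seed=9, plants_per_pop=5)
    return visits, plant


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
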