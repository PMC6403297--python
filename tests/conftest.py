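import pytest

from bridgemark import SimulationConfig, simulate_truth


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        seed=11, n_chromosomes=2, chromosome_lengths=(300_000, 300_000)
    )


@pytest.fixture(scope="session")
def truth(small_config):
    """Shared small synthetic study (two accessions, genes, 5% masked
    coverage, species panel)."""
    return simulate_truth(small_config)


@pytest.fixture(scope="session")
def clean_truth():
    """Small synthetic study with complete identity coverage (no masking),
    for oracle-equivalence checks."""
    config = SimulationConfig(
        seed=23,
        n_chromosomes=2,
        chromosome_lengths=(300_000, 300_000),
        identity_masked_fraction=0.0,
    )
    return simulate_truth(config)
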