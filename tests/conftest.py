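import pytest

from mutscreen import (
    ScreenSimConfig,
    emit_caller_callsets,
    simulate_genome,
    simulate_screen,
)


@pytest.fixture(scope="session")
def sim_config():
    return ScreenSimConfig(seed=42)


@pytest.fixture(scope="session")
def sim_genome(sim_config):
    """One deterministic synthetic genome shared across the session."""
    return simulate_genome(sim_config)


@pytest.fixture(scope="session")
def sim_screen(sim_config, sim_genome):
    genome, genes = sim_genome
    return simulate_screen(genome, genes, sim_config)


@pytest.fixture(scope="session")
def sim_callsets(sim_config, sim_genome, sim_screen):
    genome, _ = sim_genome
    return emit_caller_callsets(sim_screen, genome, sim_config)
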