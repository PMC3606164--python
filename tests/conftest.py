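import pytest
from hypothesis import settings

from oatkit import simulate

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def tiny_config():
    """Desk-size panel config shared by unit tests (full scale lives in the
    acceptance suite)."""
    return simulate.SimulationConfig(seed=11, n_templates=6)


@pytest.fixture(scope="session")
def tiny_panel(tiny_config):
    haplotypes, truth = simulate.simulate_panel(tiny_config)
    return haplotypes, truth


@pytest.fixture(scope="session")
def tiny_reads(tiny_config, tiny_panel):
    haplotypes, _ = tiny_panel
    return simulate.simulate_reads(haplotypes, tiny_config)
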