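import pytest

from gonadpipe import SimulationConfig


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A 2-gene configuration for fast exact-recovery checks."""
    return SimulationConfig(n_genes=2, n_biased_testis=0, n_biased_ovary=0,
                            reads_per_sample=40, orf_length_range=(40, 60),
                            seed=1)


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    """The study-scale conditions: 50 genes, 5,000 reads per sample."""
    return SimulationConfig(seed=1)
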