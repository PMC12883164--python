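import pytest

from genetraits.genetic_code import default_code
from genetraits.simulate import GeneratorConfig, generate_community


@pytest.fixture(scope="session")
def code():
    return default_code()


@pytest.fixture(scope="session")
def small_community():
    """A fast community for stage-level tests (6 taxa x 20 genes)."""
    cfg = GeneratorConfig(n_taxa=6, genes_per_taxon=20, seed=0)
    genes, truth, cm = generate_community(cfg)
    return cfg, genes, truth, cm


@pytest.fixture(scope="session")
def default_community():
    """The default community (30 taxa x 50 genes, seed 0) for recovery tests."""
    cfg = GeneratorConfig(seed=0)
    genes, truth, cm = generate_community(cfg)
    return cfg, genes, truth, cm
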