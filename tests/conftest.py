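import numpy as np
import pytest

from gutrefset.synthetic import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """3 species x 2 individuals x 2 assemblies, 30 kb genomes."""
    cfg = SimulationConfig(
        seed=11, n_species=3, n_individuals=2, genome_length=30_000, assemblies_per_species=2
    )
    out = tmp_path_factory.mktemp("cohort")
    return simulate_cohort(cfg, out)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
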