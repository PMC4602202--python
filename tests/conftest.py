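import pytest

from snvforest.model import CVConfig
from snvforest.simulate import UniverseConfig, generate_universe


@pytest.fixture(scope="session")
def small_config():
    """A compact universe: fast enough for unit tests, big enough for CV."""
    return UniverseConfig(
        n_genes=120,
        n_diseases=12,
        n_clusters=4,
        cluster_pool_size=18,
        module_size=6,
        n_causative_variants=60,
        n_neutral_variants=120,
        n_disease_control_variants=40,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_universe(small_config):
    return generate_universe(small_config)


@pytest.fixture(scope="session")
def pipeline_data(small_universe):
    return small_universe.to_pipeline_data()


@pytest.fixture(scope="session")
def fast_cv():
    return CVConfig(n_folds=5, n_trees=100, seed=3)
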