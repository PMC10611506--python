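import pytest

from hlanovel import fixtures
from hlanovel.impact import default_property_table, demo_eplet_registry
from hlanovel.synthetic import SimulationConfig, make_gene_model


@pytest.fixture(scope="session")
def dpa1_model():
    return fixtures.dpa1_leader_model()


@pytest.fixture(scope="session")
def b48_model():
    return fixtures.b48_model()


@pytest.fixture(scope="session")
def b56_model():
    return fixtures.b56_model()


@pytest.fixture(scope="session")
def dqa1_model():
    return fixtures.dqa1_intron_model()


@pytest.fixture(scope="session")
def property_table():
    return default_property_table()


@pytest.fixture(scope="session")
def eplet_registry():
    return demo_eplet_registry()


@pytest.fixture(scope="session")
def allele_table():
    return fixtures.load_novel_allele_table()


@pytest.fixture(scope="session")
def missense_table():
    return fixtures.load_missense_table()


@pytest.fixture(scope="session")
def reference_cohort():
    return fixtures.load_reference_cohort()


@pytest.fixture(scope="session")
def small_config():
    """Compact synthetic models so property tests stay fast."""
    return SimulationConfig(
        seed=7,
        exon_length_range=(30, 120),
        intron_length_range=(20, 80),
        utr_length_range=(0, 60),
    )


@pytest.fixture(scope="session")
def synthetic_models(small_config):
    return [make_gene_model(small_config, i) for i in range(20)]
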