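import pytest

from finid.fixtures import load_table2_fixture, load_table3_key
from finid.key import build_consensus
from finid.synthetic import SimConfig, simulate_library


@pytest.fixture(scope="session")
def table3_key():
    return load_table3_key()


@pytest.fixture(scope="session")
def table2():
    return load_table2_fixture()


@pytest.fixture(scope="session")
def cites_library(table3_key):
    """Noise-free-at-key-positions panel: 8 CITES species x 10 records."""
    cfg = SimConfig(key=table3_key,
                    species_panel=[(sp, 10) for sp in table3_key.rows],
                    seed=11)
    return simulate_library(cfg)


@pytest.fixture(scope="session")
def cites_sim_config(table3_key):
    return SimConfig(key=table3_key,
                     species_panel=[(sp, 10) for sp in table3_key.rows],
                     seed=11)


@pytest.fixture(scope="session")
def qc_library(table3_key):
    """Deeper-divergence panel for misidentification screening.

    Screening separates within- from between-species identity; the
    published examples show ~99% foreign vs 83-86% conspecific identity,
    i.e. between-species divergence well beyond 10%. A 10% per-species
    background divergence reproduces that regime.
    """
    cfg = SimConfig(key=table3_key,
                    species_panel=[(sp, 5) for sp in table3_key.rows],
                    between_species_background_divergence=0.10,
                    seed=17)
    return simulate_library(cfg)


@pytest.fixture(scope="session")
def cites_consensuses(cites_library):
    return {sp: build_consensus(cites_library.records_for(sp))
            for sp in cites_library.species()}
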