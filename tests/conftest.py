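import pytest

from arcticum import datasets
from arcticum.synthetic import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def iil6_records():
    """Two-site IIL-6 cytotype census expanded to 206 larval records."""
    return datasets.iil6_records()


@pytest.fixture(scope="session")
def rock_creek():
    """Rock Creek collection: 447 standard females, 261 carrier males."""
    return datasets.rock_creek_records()


@pytest.fixture(scope="session")
def small_dataset():
    """A small but complete synthetic survey (shared across tests)."""
    cfg = SimulationConfig(
        seed=11,
        n_siblings=3,
        n_cytotypes=5,
        n_orphan_cytotypes=1,
        sites_per_sibling=8,
        larvae_per_site=60,
        multi_taxon_fraction=0.5,
    )
    return simulate_dataset(cfg)
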