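import dataclasses

import pytest

import rediploid as rd


@pytest.fixture(scope="session")
def homology_table():
    return rd.load_coregonine_homology()


@pytest.fixture(scope="session")
def map_summary():
    return rd.load_cisco_map_summary()


@pytest.fixture(scope="session")
def fast_config():
    """Small chromosomes for unit tests; same rates as the defaults."""
    return dataclasses.replace(rd.SimConfig(), chrom_length=20_000, seed=11)


@pytest.fixture(scope="session")
def fast_panel(fast_config):
    return rd.simulate_panel(fast_config)
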