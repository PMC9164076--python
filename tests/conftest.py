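import pytest

from netpharm import datasets


@pytest.fixture(scope="session")
def roster():
    """The 32-compound antihistamine roster."""
    return datasets.antihistamine_compounds()


@pytest.fixture(scope="session")
def descriptor_frame():
    return datasets.antihistamine_descriptors()


@pytest.fixture(scope="session")
def enrichment_fixture():
    """The published 7-row enrichment table."""
    return datasets.pathway_enrichment_table()


@pytest.fixture(scope="session")
def ppi_table():
    return datasets.ppi_centrality()


@pytest.fixture(scope="session")
def subnetwork_table():
    return datasets.subnetwork_centrality()


@pytest.fixture(scope="session")
def docking_fixture():
    return datasets.docking_records()
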