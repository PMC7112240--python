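import pytest

from gnotodiet.fixtures import (
    build_reconciliation_records,
    load_flyaa_medium,
    load_network,
    load_paper_fixture,
    load_registry,
)


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def hd_medium():
    """Complete solid FLYAA holidic diet."""
    return load_flyaa_medium()


@pytest.fixture(scope="session")
def fixture_tables():
    """(PhenotypeTable, producibility DataFrame) from the committed transcription."""
    return load_paper_fixture()


@pytest.fixture(scope="session")
def reconciliation_records(fixture_tables, registry):
    phen, prod = fixture_tables
    return build_reconciliation_records(phen, prod, registry)


@pytest.fixture(scope="session")
def networks(registry):
    return {org: load_network(org, registry) for org in ("Dmel", "Ap", "Lp")}
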