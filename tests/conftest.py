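import pytest

from mipkit.fixtures import load_fixture_tables, load_motif_table, load_reference_panel
from mipkit.homology import ScoringScheme


@pytest.fixture(scope="session")
def panel():
    return load_reference_panel()


@pytest.fixture(scope="session")
def scheme():
    return ScoringScheme()


@pytest.fixture(scope="session")
def tables():
    return load_fixture_tables()


@pytest.fixture(scope="session")
def motif_table():
    return load_motif_table()
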