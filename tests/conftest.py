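import json

import pytest

from phyx import enumerate_topologies, load_phyx
from phyx.fixtures import crocodylia_document


@pytest.fixture(scope="session")
def catalogs():
    """Topology catalogs for n=2..6, enumerated once per session."""
    return {n: enumerate_topologies(n) for n in range(2, 7)}


@pytest.fixture(scope="session")
def small_catalogs(catalogs):
    """The exhaustive-check sizes (n=2..5)."""
    return {n: catalogs[n] for n in range(2, 6)}


@pytest.fixture()
def crocodylia_doc():
    return load_phyx(json.dumps(crocodylia_document()))
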