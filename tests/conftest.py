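import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracle.py importable

from gxqsar.molgraph import parse_smiles
from gxqsar.simdata import fixture_molecules


@pytest.fixture(scope="session")
def fixtures():
    """The packaged fixture molecules with frozen oracle descriptor values."""
    return fixture_molecules()


@pytest.fixture(scope="session")
def fixture_graphs(fixtures):
    return {f["name"]: parse_smiles(f["smiles"]) for f in fixtures}
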