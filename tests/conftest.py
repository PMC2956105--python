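import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from erqsar import compute_matrix, load_fixture
from erqsar.structures import MolecularStructure, embed_conformer


@pytest.fixture(scope="session")
def fixture_table():
    return load_fixture()


@pytest.fixture(scope="session")
def core_matrix(fixture_table):
    """Core 11-descriptor matrix of the 82-compound study set (computed once)."""
    return compute_matrix(fixture_table)


SMALL_SMILES = {
    "ethane": "CC",
    "propane": "CCC",
    "n-pentane": "CCCCC",
    "ethanol": "CCO",
    "fluoroethene": "C=CF",
    "acetamide": "CC(N)=O",
    "benzene": "c1ccccc1",
}


@pytest.fixture(scope="session")
def small_structures():
    """Embedded conformers for a panel of small (<= 6 heavy atoms) molecules."""
    out = {}
    for name, smi in SMALL_SMILES.items():
        struct = embed_conformer(MolecularStructure.from_smiles(smi), seed=11)
        assert not struct.embed_failed
        out[name] = struct
    return out
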