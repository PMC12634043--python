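import pytest

from cgweaver.ffdata import load_forcefield
from cgweaver.fixtures import FixtureSpec, make_structure
from cgweaver.ledger import WarningLedger


@pytest.fixture(scope="session")
def aa_ff():
    ff, _ = load_forcefield("demo-aa")
    return ff


@pytest.fixture(scope="session")
def cg_ff():
    ff, _ = load_forcefield("demo-cg")
    return ff


@pytest.fixture(scope="session")
def cg_mappings():
    _, mappings = load_forcefield("demo-cg")
    return mappings


@pytest.fixture
def ledger():
    return WarningLedger()


@pytest.fixture
def peptide_record():
    record, manifest = make_structure(FixtureSpec("linear_peptide", n_residues=6))
    return record, manifest


@pytest.fixture
def disulfide_record():
    record, manifest = make_structure(FixtureSpec("two_chain_disulfide"))
    return record, manifest
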