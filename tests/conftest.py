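import pytest

from focuslib.curation import MoleculeRecord, standardize_record
from focuslib.fixtures import FixtureSpec, builtin_rules, default_probes, make_seed_set


def record(smiles: str, source_id: str = "") -> MoleculeRecord:
    rec = standardize_record(smiles, source_id=source_id)
    assert isinstance(rec, MoleculeRecord), f"fixture SMILES failed curation: {smiles}"
    return rec


@pytest.fixture(scope="session")
def compendium():
    return builtin_rules()


@pytest.fixture(scope="session")
def probes():
    return default_probes()


@pytest.fixture(scope="session")
def toluene():
    return record("Cc1ccccc1", "toluene")


@pytest.fixture(scope="session")
def cyclohexane():
    return record("C1CCCCC1", "cyclohexane")


@pytest.fixture(scope="session")
def motif_seeds():
    return make_seed_set(
        FixtureSpec(motifs={"phenyl": 2, "carboxylic-acid": 2}, decoration_depth=1, seed=11)
    )


@pytest.fixture(scope="session")
def panel():
    """Ten structurally varied drug-like molecules for scoring tests."""
    smiles = [
        "CC(=O)Oc1ccccc1C(=O)O",                    # aspirin
        "CC(C)Cc1ccc(C(C)C(=O)O)cc1",               # ibuprofen
        "CN1C=NC2=C1C(=O)N(C)C(=O)N2C",             # caffeine
        "NC(=O)c1ccc[nH]1",
        "CCN(CC)C(=O)c1ccccc1",
        "Oc1ccc(CCN)cc1",
        "CC1CCCCC1",
        "O=C1NC(=O)C(Cc2ccc(OCc3ccccc3)cc2)S1",     # benzyl-ether TZD
        "COc1ccc2cc(C(C)C(=O)O)ccc2c1",             # naproxen-like
        "CS(=O)(=O)c1ccc(-c2ccccc2)cc1",
    ]
    return [record(s, f"panel-{i}") for i, s in enumerate(smiles)]
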