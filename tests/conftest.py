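import random

import pytest
from rdkit import Chem

from chemtaxon.fixtures.golden import build_golden_corpus
from chemtaxon.fixtures.seed_rules import get_seed_ruleset
from chemtaxon.fixtures.seed_taxonomy import get_seed_taxonomy


@pytest.fixture(scope="session")
def tax():
    return get_seed_taxonomy()


@pytest.fixture(scope="session")
def rs():
    return get_seed_ruleset()


@pytest.fixture(scope="session")
def golden():
    return build_golden_corpus()


def permute_smiles(smiles: str, rng: random.Random) -> str:
    """A SMILES spelling of the same molecule with shuffled atom order."""
    mol = Chem.MolFromSmiles(smiles)
    order = list(range(mol.GetNumAtoms()))
    rng.shuffle(order)
    return Chem.MolToSmiles(Chem.RenumberAtoms(mol, order), canonical=False)
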