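import pathlib

import pytest
from hypothesis import settings

settings.register_profile("derandomized", deadline=None, derandomize=True)
settings.load_profile("derandomized")

DATA = pathlib.Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def matcher():
    from wlnkit.fsm import build_matcher

    return build_matcher()


@pytest.fixture(scope="session")
def smith_tsv():
    import importlib.resources as ir

    return str(ir.files("wlnkit") / "data" / "synthetic_smith.tsv")


@pytest.fixture(scope="session")
def curation_tsv():
    import importlib.resources as ir

    return str(ir.files("wlnkit") / "data" / "synthetic_curation.tsv")


@pytest.fixture(scope="session")
def smith_pairs(smith_tsv):
    pairs = []
    with open(smith_tsv) as fh:
        for line in fh:
            wln, smi = line.rstrip("\n").split("\t")
            pairs.append((wln, smi))
    return pairs


def canonical(smiles: str) -> str:
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    assert mol is not None, smiles
    return Chem.MolToSmiles(mol)


@pytest.fixture(scope="session")
def can():
    return canonical
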