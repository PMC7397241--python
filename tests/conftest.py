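from pathlib import Path

import pytest

from kinasespace.chemio import DatasetLabel, MoleculeRecord
from kinasespace.synthdata import default_library_spec, generate_library

DATA_DIR = Path(__file__).parent / "data"


def record_from_smiles(smiles: str, id: str = "m0", label=DatasetLabel.OTHER) -> MoleculeRecord:
    """A minimal standardized record built straight from a SMILES string."""
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    assert mol is not None, smiles
    canon = Chem.MolToSmiles(mol)
    return MoleculeRecord(
        id=id, smiles_input=smiles, smiles_std=canon,
        inchikey=Chem.MolToInchiKey(mol), dataset_label=label,
    )


def records_from_smiles(smiles_list) -> list[MoleculeRecord]:
    return [record_from_smiles(s, id=f"m{i}") for i, s in enumerate(smiles_list)]


@pytest.fixture(scope="session")
def planted_library():
    """The default 100-molecule planted library and its construction truth."""
    return generate_library(default_library_spec(seed=11))


@pytest.fixture(scope="session")
def small_library():
    """A 20-molecule slice of the planted library for slower stages."""
    records, _ = generate_library(default_library_spec(seed=5))
    return records[::5]
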