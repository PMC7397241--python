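"""Conformer generation and principal-moments-of-inertia shape analysis.

One low-energy 3D conformer per molecule is produced by distance-geometry
embedding (ETKDG) followed by MMFF94 minimization; the lowest-energy
conformer of ``n_confs`` trials is kept.  Shape is summarized by the
normalized principal moment ratios NPR1 = I1/I3 and NPR2 = I2/I3, which
place every molecule inside the triangle spanned by the rod (diacetylene,
(0, 1)), the disc (benzene, (0.5, 0.5)) and the sphere (adamantane,
(1, 1)).  Moments are mass-weighted and include hydrogens.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem

from .chemio import MoleculeRecord

logger = logging.getLogger(__name__)

__all__ = [
    "PMIPoint",
    "REFERENCE_MOLECULES",
    "embed_conformer",
    "pmi_point",
    "pmi_from_record",
    "pmi_table",
]

#: Reference shapes delimiting the PMI triangle vertices.
REFERENCE_MOLECULES = {
    "diacetylene": "C#CC#C",   # rod, NPR ~ (0, 1)
    "benzene": "c1ccccc1",     # disc, NPR ~ (0.5, 0.5)
    "adamantane": "C1C2CC3CC1CC(C2)C3",  # sphere, NPR ~ (1, 1)
}


@dataclass
class PMIPoint:
    I1: float
    I2: float
    I3: float
    NPR1: float
    NPR2: float
    energy: float = float("nan")  # kcal/mol, MMFF94
    seed: int = 0

    def check(self) -> None:
        assert 0.0 <= self.I1 <= self.I2 <= self.I3
        assert -1e-9 <= self.NPR1 <= self.NPR2 <= 1.0 + 1e-9
        assert self.NPR1 + self.NPR2 >= 1.0 - 1e-9


def embed_conformer(
    record: "MoleculeRecord | str", n_confs: int = 10, seed: int = 42
) -> tuple[Chem.Mol, int, float]:
    """Embed ``n_confs`` conformers, minimize each, return the best.

    Returns ``(mol_with_hydrogens, conformer_id, energy)``.  Deterministic
    for a given (structure, n_confs, seed).  Raises ``RuntimeError`` when
    embedding fails for every trial.
    """
    if n_confs < 1:
        raise ValueError("n_confs must be >= 1")
    smiles = record.smiles_std or record.smiles_input if isinstance(record, MoleculeRecord) else record
    mol = Chem.MolFromSmiles(smiles)
    if mol is None or mol.GetNumHeavyAtoms() < 1:
        raise ValueError(f"cannot embed structure {smiles!r}")
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv2()
    params.randomSeed = seed
    conf_ids = AllChem.EmbedMultipleConfs(mol, numConfs=n_confs, params=params)
    if len(conf_ids) == 0:
        # retry with random-coordinate initialization before giving up
        params.useRandomCoords = True
        conf_ids = AllChem.EmbedMultipleConfs(mol, numConfs=n_confs, params=params)
    if len(conf_ids) == 0:
        raise RuntimeError(f"conformer embedding failed for {smiles!r}")
    results = AllChem.MMFFOptimizeMoleculeConfs(mol)
    energies = np.array([e for _converged, e in results], dtype=float)
    best = int(np.argmin(energies))
    return mol, int(conf_ids[best]), float(energies[best])


def pmi_point(coords: np.ndarray, masses: np.ndarray, *, energy: float = float("nan"),
              seed: int = 0) -> PMIPoint:
    """Principal moments of inertia of a mass-weighted point set.

    The inertia tensor is taken about the center of mass; eigenvalues are
    sorted ascending and the NPR ratios formed from them.
    """
    coords = np.asarray(coords, dtype=float)
    masses = np.asarray(masses, dtype=float)
    if coords.shape[0] < 2:
        raise ValueError("need at least two atoms")
    com = (masses[:, None] * coords).sum(axis=0) / masses.sum()
    r = coords - com
    if np.allclose(r, 0.0):
        raise ValueError("degenerate geometry: all atoms coincident")
    r2 = (r**2).sum(axis=1)
    tensor = np.eye(3) * np.sum(masses * r2) - np.einsum("i,ij,ik->jk", masses, r, r)
    moments = np.sort(np.linalg.eigvalsh(tensor))
    moments = np.clip(moments, 0.0, None)  # numerical noise on linear molecules
    point = PMIPoint(
        I1=float(moments[0]),
        I2=float(moments[1]),
        I3=float(moments[2]),
        NPR1=float(moments[0] / moments[2]),
        NPR2=float(moments[1] / moments[2]),
        energy=energy,
        seed=seed,
    )
    point.check()
    return point


def pmi_from_record(record: "MoleculeRecord | str", n_confs: int = 10, seed: int = 42) -> PMIPoint:
    """Embed one molecule and compute its PMI point."""
    mol, conf_id, energy = embed_conformer(record, n_confs=n_confs, seed=seed)
    coords = mol.GetConformer(conf_id).GetPositions()
    masses = np.array([a.GetMass() for a in mol.GetAtoms()])
    return pmi_point(coords, masses, energy=energy, seed=seed)


def pmi_table(
    records: Sequence[MoleculeRecord], n_confs: int = 10, seed: int = 42,
    include_references: bool = True,
) -> pd.DataFrame:
    """PMI points for a molecule set, with the three reference shapes appended.

    Molecules whose embedding fails are excluded with a logged reason,
    never failing the batch.
    """
    rows = []
    for rec in records:
        try:
            p = pmi_from_record(rec, n_confs=n_confs, seed=seed)
        except (RuntimeError, ValueError) as exc:
            logger.warning("PMI skipped for %s: %s", rec.id, exc)
            continue
        rows.append(
            {"id": rec.id, "I1": p.I1, "I2": p.I2, "I3": p.I3, "NPR1": p.NPR1,
             "NPR2": p.NPR2, "energy": p.energy,
             "dataset_label": rec.dataset_label.value}
        )
    if include_references:
        for name, smiles in REFERENCE_MOLECULES.items():
            p = pmi_from_record(smiles, n_confs=n_confs, seed=seed)
            rows.append(
                {"id": name, "I1": p.I1, "I2": p.I2, "I3": p.I3, "NPR1": p.NPR1,
                 "NPR2": p.NPR2, "energy": p.energy, "dataset_label": "REFERENCE"}
            )
    return pd.DataFrame(rows, columns=["id", "I1", "I2", "I3", "NPR1", "NPR2", "energy", "dataset_label"])
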