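"""Bemis–Murcko scaffolds, graph frameworks, macrocycles and diversity stats.

The Bemis–Murcko (BM) scaffold of a molecule is its ring systems plus the
linkers connecting them, with side chains removed; atoms double-bonded
directly to the scaffold (exocyclic =O, =N) are retained.  The graph
framework abstracts the BM scaffold further by turning every atom into
carbon and every bond into a single bond, so scaffolds differing only in
heteroatoms or bond orders collapse onto one cyclic skeleton.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

from .chemio import MoleculeRecord
from .similarity import pairwise_similarity

__all__ = [
    "ScaffoldRecord",
    "DiversityStats",
    "bm_scaffold",
    "graph_framework",
    "detect_macrocycle",
    "scaffold_records",
    "diversity_stats",
    "scaffold_match",
]


@dataclass
class ScaffoldRecord:
    molecule_id: str
    bm_smiles: str          # empty for acyclic molecules
    gf_smiles: str          # empty iff bm_smiles is empty
    is_macrocyclic: bool


@dataclass
class DiversityStats:
    n_molecules: int
    n_macrocycles: int
    n_unique_bm: int
    n_unique_gf: int
    similarity_mean: Optional[float]
    similarity_sd: Optional[float]

    @property
    def pct_macrocycles(self) -> float:
        return 100.0 * self.n_macrocycles / self.n_molecules

    @property
    def pct_unique_bm(self) -> float:
        return 100.0 * self.n_unique_bm / self.n_molecules

    @property
    def pct_unique_gf(self) -> float:
        return 100.0 * self.n_unique_gf / self.n_molecules

    @property
    def molecules_per_bm(self) -> float:
        return self.n_molecules / self.n_unique_bm if self.n_unique_bm else float("nan")

    @property
    def molecules_per_gf(self) -> float:
        return self.n_molecules / self.n_unique_gf if self.n_unique_gf else float("nan")


def _as_mol(record: "MoleculeRecord | Chem.Mol | str") -> Chem.Mol:
    if isinstance(record, MoleculeRecord):
        mol = record.to_mol()
    elif isinstance(record, str):
        mol = Chem.MolFromSmiles(record)
    else:
        mol = record
    if mol is None:
        raise ValueError("invalid structure")
    return mol


def bm_scaffold(record: "MoleculeRecord | Chem.Mol | str") -> str:
    """Canonical Bemis–Murcko scaffold; empty string for acyclic molecules."""
    mol = _as_mol(record)
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    if scaffold is None or scaffold.GetNumAtoms() == 0:
        return ""
    return Chem.MolToSmiles(scaffold)


def graph_framework(bm: str) -> str:
    """Graph framework (cyclic skeleton) of a BM scaffold string."""
    if not bm:
        return ""
    mol = Chem.MolFromSmiles(bm)
    if mol is None:
        raise ValueError(f"invalid scaffold {bm!r}")
    generic = MurckoScaffold.MakeScaffoldGeneric(mol)
    return Chem.MolToSmiles(generic)


MACROCYCLE_MIN_RING = 13  # smallest ring size counted as macrocyclic (> 12 atoms)


def detect_macrocycle(record: "MoleculeRecord | Chem.Mol | str") -> bool:
    """True iff some SSSR ring has more than 12 atoms.

    The rule applies to the smallest set of smallest rings strictly, so a
    large fused envelope (e.g., naphthalene's 10-atom perimeter) does not
    count.
    """
    mol = _as_mol(record)
    return any(len(ring) >= MACROCYCLE_MIN_RING for ring in mol.GetRingInfo().AtomRings())


def scaffold_records(records: Sequence[MoleculeRecord]) -> list[ScaffoldRecord]:
    out = []
    for rec in records:
        bm = bm_scaffold(rec)
        out.append(
            ScaffoldRecord(
                molecule_id=rec.id,
                bm_smiles=bm,
                gf_smiles=graph_framework(bm),
                is_macrocyclic=detect_macrocycle(rec),
            )
        )
    return out


def diversity_stats(records: Sequence[MoleculeRecord]) -> DiversityStats:
    """Scaffold diversity and pairwise-similarity summary for one dataset.

    Similarity is the Tanimoto coefficient on 166-bit structural keys over
    all unordered within-dataset pairs; for a single molecule it is
    reported as absent.
    """
    if len(records) == 0:
        raise ValueError("diversity_stats requires a non-empty set")
    scaffolds = scaffold_records(records)
    if len(records) >= 2:
        sim = pairwise_similarity(records, "structural_keys_166")
        sim_mean, sim_sd = sim.mean, sim.sd
    else:
        sim_mean = sim_sd = None
    return DiversityStats(
        n_molecules=len(records),
        n_macrocycles=sum(s.is_macrocyclic for s in scaffolds),
        n_unique_bm=len({s.bm_smiles for s in scaffolds}),
        n_unique_gf=len({s.gf_smiles for s in scaffolds}),
        similarity_mean=sim_mean,
        similarity_sd=sim_sd,
    )


def scaffold_match(
    query_scaffolds: "set[str] | Sequence[str]",
    library: Sequence[MoleculeRecord],
    level: str = "bm",
) -> tuple[dict[str, int], int]:
    """Count library molecules whose scaffold equals each query scaffold.

    ``level`` chooses BM-scaffold or graph-framework equality.  Both sides
    are re-canonicalized before comparison so canonical-form drift cannot
    produce false misses.  Returns ``(per-query hit counts, total matched
    molecules)``; the total counts each molecule once even if several
    queries match it.
    """
    if level not in ("bm", "gf"):
        raise ValueError("level must be 'bm' or 'gf'")

    def canon(s: str) -> str:
        return Chem.CanonSmiles(s) if s else ""

    queries = {canon(q) for q in query_scaffolds}
    hits = {q: 0 for q in queries}
    matched_molecules = 0
    for rec in library:
        bm = bm_scaffold(rec)
        key = canon(bm if level == "bm" else graph_framework(bm))
        if key in hits:
            hits[key] += 1
            matched_molecules += 1
    return hits, matched_molecules
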