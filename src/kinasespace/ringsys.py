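"""Ring-system ensemble extraction and encoding.

A ring-system ensemble is a maximal group of fused rings: SSSR rings
sharing at least one atom are merged into one system (so spiro junctions
fuse by default; a ``fusion="bond"`` switch restricts merging to rings
sharing a bond).  Rings joined only through acyclic bonds — biphenyl —
are separate systems.

Each system is encoded twice:

* **unpositioned** — every acyclic substituent, including exocyclic
  double-bonded atoms, is replaced by hydrogen and aromaticity is
  re-perceived.  Removing an amide carbonyl this way can legitimately
  de-aromatize a ring (an oxindole's ring system becomes the non-aromatic
  indoline).
* **positioned** — atoms double-bonded to the system (exocyclic =O, =N,
  =C) are retained unchanged; every other first attached atom is replaced
  by a typed dummy encoded as atom map 1–4: 1 = generic (not aromatic,
  not in a ring, not halogen), 2 = non-aromatic ring atom, 3 = aromatic
  atom, 4 = halogen.

The typing rules are applied in the precedence retained > halogen >
aromatic > non-aromatic ring > generic, which makes the classes a
partition.  "Not double bonded" refers to the bond linking the atom to
the ring system: an acyl carbon, double-bonded only to its own oxygen,
is a generic (class 1) attachment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from rdkit import Chem

from .chemio import MoleculeRecord

logger = logging.getLogger(__name__)

__all__ = [
    "RingSystem",
    "FrequencyTable",
    "ring_system_atom_sets",
    "extract_ring_systems",
    "encode_unpositioned",
    "encode_positioned",
    "strip_positioned",
    "bicycle_frequency",
    "bicycle_prevalence",
]

_HALOGENS = {9, 17, 35, 53, 85}


@dataclass
class RingSystem:
    molecule_id: str
    unpositioned: str
    positioned: str
    n_rings: int
    atom_indices: frozenset[int] = field(default_factory=frozenset, repr=False)
    retained_exocyclic: tuple[int, ...] = ()

    @property
    def is_bicycle(self) -> bool:
        return self.n_rings == 2


@dataclass
class FrequencyTable:
    """Canonical structure → (count, frequency) with singleton accounting."""

    entries: dict[str, tuple[int, float]]
    n_total: int
    n_unique: int
    n_singletons: int

    @classmethod
    def from_keys(cls, keys: Iterable[str]) -> "FrequencyTable":
        counts: dict[str, int] = {}
        for k in keys:
            counts[k] = counts.get(k, 0) + 1
        total = sum(counts.values())
        entries = {k: (c, c / total if total else 0.0) for k, c in counts.items()}
        return cls(
            entries=entries,
            n_total=total,
            n_unique=len(counts),
            n_singletons=sum(1 for c in counts.values() if c == 1),
        )

    def top(self, k: int) -> list[tuple[str, int, float]]:
        """Top-k entries by count, ties broken lexicographically on the key."""
        ranked = sorted(self.entries.items(), key=lambda kv: (-kv[1][0], kv[0]))
        return [(key, c, f) for key, (c, f) in ranked[:k]]


def ring_system_atom_sets(mol: Chem.Mol, fusion: str = "atom") -> list[set[int]]:
    """Partition the molecule's ring atoms into fused ring systems."""
    if fusion not in ("atom", "bond"):
        raise ValueError("fusion must be 'atom' or 'bond'")
    min_shared = 1 if fusion == "atom" else 2
    systems: list[tuple[set[int], int]] = []  # (atom set, ring count)
    for ring in mol.GetRingInfo().AtomRings():
        merged, n_rings = set(ring), 1
        keep = []
        for atoms, k in systems:
            if len(atoms & merged) >= min_shared:
                merged |= atoms
                n_rings += k
            else:
                keep.append((atoms, k))
        systems = keep + [(merged, n_rings)]
    return [atoms for atoms, _ in systems]


def _ring_counts(mol: Chem.Mol, systems: Sequence[set[int]]) -> list[int]:
    counts = [0] * len(systems)
    for ring in mol.GetRingInfo().AtomRings():
        for i, atoms in enumerate(systems):
            if set(ring) <= atoms:
                counts[i] += 1
                break
    return counts


def _kekulized_copy(mol: Chem.Mol) -> Chem.RWMol:
    em = Chem.RWMol(mol)
    Chem.Kekulize(em, clearAromaticFlags=True)
    return em


def _finish(em: Chem.RWMol) -> str:
    m = em.GetMol()
    Chem.SanitizeMol(m)
    Chem.RemoveStereochemistry(m)
    return Chem.MolToSmiles(m)


def encode_unpositioned(mol: Chem.Mol, atoms: set[int]) -> str:
    """Canonical form of the bare ring system, substituents → hydrogen."""
    em = _kekulized_copy(mol)
    for idx in sorted((a.GetIdx() for a in mol.GetAtoms() if a.GetIdx() not in atoms), reverse=True):
        em.RemoveAtom(idx)
    return _finish(em)


def _retained_exocyclic(mol: Chem.Mol, atoms: set[int]) -> set[int]:
    retained = set()
    for idx in atoms:
        for bond in mol.GetAtomWithIdx(idx).GetBonds():
            other = bond.GetOtherAtom(mol.GetAtomWithIdx(idx))
            if other.GetIdx() not in atoms and bond.GetBondTypeAsDouble() >= 2.0:
                retained.add(other.GetIdx())
    return retained


def encode_positioned(mol: Chem.Mol, atoms: set[int]) -> tuple[str, tuple[int, ...]]:
    """Canonical ring system with typed dummy attachment points.

    Returns ``(smiles, retained_exocyclic_atom_indices)``.
    """
    retained = _retained_exocyclic(mol, atoms)
    core = atoms | retained
    shell: dict[int, int] = {}
    for idx in core:
        atom = mol.GetAtomWithIdx(idx)
        for bond in atom.GetBonds():
            other = bond.GetOtherAtom(atom)
            j = other.GetIdx()
            if j in core:
                continue
            if other.GetAtomicNum() in _HALOGENS:
                cls = 4
            elif other.GetIsAromatic():
                cls = 3
            elif other.IsInRing():
                cls = 2
            else:
                cls = 1
            shell[j] = cls
    em = _kekulized_copy(mol)
    for j, cls in shell.items():
        atom = em.GetAtomWithIdx(j)
        atom.SetAtomicNum(0)
        atom.SetFormalCharge(0)
        atom.SetNoImplicit(True)
        atom.SetNumExplicitHs(0)
        atom.SetAtomMapNum(cls)
        for bond in atom.GetBonds():
            bond.SetBondType(Chem.BondType.SINGLE)
    keep = core | set(shell)
    for idx in sorted((a.GetIdx() for a in mol.GetAtoms() if a.GetIdx() not in keep), reverse=True):
        em.RemoveAtom(idx)
    return _finish(em), tuple(sorted(retained))


def strip_positioned(positioned: str) -> str:
    """Project a positioned encoding onto its unpositioned form.

    Deletes all dummy atoms and retained exocyclic atoms (atoms outside
    the ring system), then re-perceives aromaticity; the result equals the
    system's unpositioned encoding.
    """
    mol = Chem.MolFromSmiles(positioned)
    if mol is None:
        raise ValueError(f"invalid positioned encoding {positioned!r}")
    drop = {a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() == 0 or not a.IsInRing()}
    em = _kekulized_copy(mol)
    for idx in sorted(drop, reverse=True):
        em.RemoveAtom(idx)
    return _finish(em)


def extract_ring_systems(
    record: "MoleculeRecord | Chem.Mol | str", fusion: str = "atom"
) -> list[RingSystem]:
    """Extract and encode every fused ring system of a molecule.

    Acyclic molecules yield an empty list.  A system whose encoding fails
    valence repair is excluded with a logged reason.
    """
    if isinstance(record, MoleculeRecord):
        mol, mol_id = record.to_mol(), record.id
    elif isinstance(record, str):
        mol, mol_id = Chem.MolFromSmiles(record), record
    else:
        mol, mol_id = record, ""
    if mol is None:
        raise ValueError("invalid structure")
    systems = ring_system_atom_sets(mol, fusion)
    counts = _ring_counts(mol, systems)
    out = []
    for atoms, n_rings in zip(systems, counts):
        try:
            unpos = encode_unpositioned(mol, atoms)
            pos, retained = encode_positioned(mol, atoms)
        except Exception as exc:
            logger.warning("ring system of %s excluded (encoding failed: %s)", mol_id, exc)
            continue
        out.append(
            RingSystem(
                molecule_id=mol_id,
                unpositioned=unpos,
                positioned=pos,
                n_rings=n_rings,
                atom_indices=frozenset(atoms),
                retained_exocyclic=retained,
            )
        )
    return out


def bicycle_frequency(
    records: Sequence[MoleculeRecord], mode: str = "unpositioned", fusion: str = "atom"
) -> FrequencyTable:
    """Occurrence-frequency table of bicyclic ring systems (two fused rings).

    A molecule contributes one count per bicycle occurrence, so a library
    may hold more bicycles than molecules.
    """
    if mode not in ("unpositioned", "positioned"):
        raise ValueError("mode must be 'unpositioned' or 'positioned'")
    keys = []
    for rec in records:
        for system in extract_ring_systems(rec, fusion):
            if system.is_bicycle:
                keys.append(getattr(system, mode))
    return FrequencyTable.from_keys(keys)


def bicycle_prevalence(records: Sequence[MoleculeRecord], fusion: str = "atom") -> float:
    """Fraction of molecules containing at least one bicyclic ring system."""
    if len(records) == 0:
        raise ValueError("bicycle_prevalence requires a non-empty set")
    n_with = sum(
        any(s.is_bicycle for s in extract_ring_systems(rec, fusion)) for rec in records
    )
    return n_with / len(records)
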