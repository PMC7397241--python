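"""Seeded synthetic molecule libraries and descriptor tables with planted truth.

The library generator decorates a pool of known ring-system cores with
substituents at known multiplicities, so scaffold counts, ring-system
frequency tables (both encodings), macrocycle counts, bicycle prevalence
and rule-violation distributions are all known from the construction
itself.  The planted-truth bookkeeping is computed while each molecule is
assembled — directly from the construction plan and elementary RDKit
calls — never by running the analysis code it is meant to check.

Defaults mirror the ring vocabulary of kinase-inhibitor libraries
(quinazoline, quinoline, indole, purine, oxindole cores; roughly 65% of
molecules carrying a fused bicycle; a couple of macrocycles) and a
substituent pool that exercises all four positioned-attachment classes
plus the exocyclic-carbonyl retention rule (via the oxindole core).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors, Lipinski

from .chemio import DatasetLabel, MoleculeRecord

__all__ = [
    "ScaffoldSpec",
    "Substituent",
    "LibrarySpec",
    "PlantedTruth",
    "default_library_spec",
    "generate_library",
    "generate_descriptor_table",
]


@dataclass(frozen=True)
class ScaffoldSpec:
    """One decoratable core and how often it appears in the library.

    ``unpositioned`` is the hand-stated bare-ring-system key of the core
    (what remains after all substituents, including exocyclic double-bonded
    atoms, are replaced by hydrogen); it defaults to the core itself and
    must be stated explicitly for cores carrying exocyclic decorations
    (oxindole's ring system is indoline).
    """

    smiles: str
    multiplicity: int
    n_rings: int
    unpositioned: Optional[str] = None
    is_macrocycle: bool = False
    decorate: bool = True

    def unpositioned_key(self) -> str:
        return Chem.CanonSmiles(self.unpositioned or self.smiles)


@dataclass(frozen=True)
class Substituent:
    smiles: str          # fragment; atom 0 is the attachment atom
    attach_class: int    # expected positioned-encoding class, 1-4
    has_ring: bool = False
    carbon_only: bool = False  # chemistry guard: only attach to ring carbons


@dataclass
class LibrarySpec:
    scaffold_pool: list[ScaffoldSpec]
    substituent_pool: list[Substituent]
    n_substituents_range: tuple[int, int] = (1, 3)
    seed: int = 0

    def n_molecules(self) -> int:
        return sum(s.multiplicity for s in self.scaffold_pool)


@dataclass
class PlantedTruth:
    """Known-answer tables derived from the construction plan."""

    n_molecules: int
    expected_bm_counts: dict[str, int] = field(default_factory=dict)
    expected_bicycle_counts_unpositioned: dict[str, int] = field(default_factory=dict)
    expected_bicycle_counts_positioned: dict[str, int] = field(default_factory=dict)
    expected_macrocycles: int = 0
    expected_violation_distribution: dict[str, int] = field(default_factory=dict)
    expected_bicycle_prevalence: float = 0.0

    @property
    def expected_bicycle_singletons_unpositioned(self) -> int:
        return sum(1 for c in self.expected_bicycle_counts_unpositioned.values() if c == 1)

    @property
    def expected_bicycle_singletons_positioned(self) -> int:
        return sum(1 for c in self.expected_bicycle_counts_positioned.values() if c == 1)


def default_library_spec(seed: int = 0, scale: int = 1) -> LibrarySpec:
    """The standard planted library: 100·scale molecules, 65% bearing a bicycle."""
    pool = [
        ScaffoldSpec("c1ccc2ncncc2c1", 25, 2),                       # quinazoline
        ScaffoldSpec("c1ccc2ncccc2c1", 15, 2),                       # quinoline
        ScaffoldSpec("c1ccc2[nH]ccc2c1", 10, 2),                     # indole
        ScaffoldSpec("c1ncc2[nH]cnc2n1", 8, 2),                      # purine
        ScaffoldSpec("O=C1Cc2ccccc2N1", 7, 2,
                     unpositioned="C1Cc2ccccc2N1"),                  # oxindole -> indoline
        ScaffoldSpec("c1ccccc1", 14, 1),                             # benzene
        ScaffoldSpec("c1ccncc1", 11, 1),                             # pyridine
        ScaffoldSpec("c1cncnc1", 8, 1),                              # pyrimidine
        ScaffoldSpec("C1CCCCCCCCCCCC1", 2, 1, is_macrocycle=True,
                     decorate=False),                                # 13-membered macrocycle
    ]
    substituents = [
        Substituent("C", 1),                                  # methyl
        Substituent("OC", 1, carbon_only=True),               # methoxy (O attaches)
        Substituent("N(C)C", 1, carbon_only=True),            # dimethylamino
        Substituent("C1CCCCC1", 2, has_ring=True),            # cyclohexyl
        Substituent("c1ccccc1", 3, has_ring=True),            # phenyl
        Substituent("F", 4, carbon_only=True),
        Substituent("Cl", 4, carbon_only=True),
        Substituent("Br", 4, carbon_only=True),
    ]
    pool = [
        ScaffoldSpec(s.smiles, s.multiplicity * scale, s.n_rings, s.unpositioned,
                     s.is_macrocycle, s.decorate)
        for s in pool
    ]
    return LibrarySpec(scaffold_pool=pool, substituent_pool=substituents, seed=seed)


def _attachable_positions(core: Chem.Mol) -> list[int]:
    """Ring atoms able to accept one more single-bonded substituent."""
    return [
        a.GetIdx()
        for a in core.GetAtoms()
        if a.IsInRing() and a.GetTotalNumHs() >= 1
    ]


def _consume_h(em: Chem.RWMol, pos: int) -> None:
    # an explicit H (e.g., pyrrole-type [nH]) must make room for the new bond
    atom = em.GetAtomWithIdx(pos)
    if atom.GetNumExplicitHs() > 0:
        atom.SetNumExplicitHs(atom.GetNumExplicitHs() - 1)


def _attach(em: Chem.RWMol, pos: int, frag: Chem.Mol) -> None:
    """Graft a fragment onto position ``pos`` via a single bond to frag atom 0."""
    offset = em.GetNumAtoms()
    for atom in frag.GetAtoms():
        em.AddAtom(atom)
    for bond in frag.GetBonds():
        em.AddBond(offset + bond.GetBeginAtomIdx(), offset + bond.GetEndAtomIdx(),
                   bond.GetBondType())
    _consume_h(em, pos)
    em.AddBond(pos, offset, Chem.BondType.SINGLE)


def _canonical(em: Chem.RWMol) -> str:
    mol = em.GetMol()
    Chem.SanitizeMol(mol)
    return Chem.MolToSmiles(mol)


def _dummy(cls: int) -> Chem.Atom:
    atom = Chem.Atom(0)
    atom.SetNoImplicit(True)
    atom.SetAtomMapNum(cls)
    return atom


def _positioned_key(core: Chem.Mol, attachments: Sequence[tuple[int, Substituent]]) -> str:
    """Expected positioned encoding of the core: typed dummies at the chosen sites."""
    em = Chem.RWMol(core)
    for pos, sub in attachments:
        idx = em.AddAtom(_dummy(sub.attach_class))
        _consume_h(em, pos)
        em.AddBond(pos, idx, Chem.BondType.SINGLE)
    return _canonical(em)


def _ring_substituent_keys(core: Chem.Mol, attachments) -> list[tuple[str, str]]:
    """(unpositioned, positioned) keys of each ring-bearing substituent."""
    keys = []
    for pos, sub in attachments:
        if not sub.has_ring:
            continue
        core_atom = core.GetAtomWithIdx(pos)
        cls = 3 if core_atom.GetIsAromatic() else 2
        ring = Chem.MolFromSmiles(sub.smiles)
        em = Chem.RWMol(ring)
        idx = em.AddAtom(_dummy(cls))
        em.AddBond(0, idx, Chem.BondType.SINGLE)
        keys.append((Chem.CanonSmiles(sub.smiles), _canonical(em)))
    return keys


def _expected_bm(core: Chem.Mol, attachments) -> str:
    """Expected BM scaffold: the core with only its ring-bearing substituents."""
    em = Chem.RWMol(core)
    for pos, sub in attachments:
        if sub.has_ring:
            _attach(em, pos, Chem.MolFromSmiles(sub.smiles))
    return _canonical(em)


def _violation_class(mol: Chem.Mol) -> str:
    """Rule-of-five violation class, re-derived from first principles."""
    n = sum(
        [
            Descriptors.MolWt(mol) > 500.0,
            Descriptors.MolLogP(mol) > 5.0,
            Lipinski.NOCount(mol) > 10,
            Lipinski.NHOHCount(mol) > 5,
        ]
    )
    return str(n) if n <= 2 else ">2"


def generate_library(spec: LibrarySpec) -> tuple[list[MoleculeRecord], PlantedTruth]:
    """Generate a decorated library and its planted truth.

    Deterministic for a fixed spec and seed.  Every emitted structure is
    round-trip parseable; a chemically impossible attachment plan is
    re-drawn (bounded retries) before the molecule falls back to the bare
    core, with the truth adjusted accordingly.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.n_substituents_range
    if lo < 0 or hi < lo:
        raise ValueError("invalid n_substituents_range")
    records: list[MoleculeRecord] = []
    truth = PlantedTruth(n_molecules=spec.n_molecules())
    n_bicycle_bearing = 0
    counter = 0
    for scaffold in spec.scaffold_pool:
        core = Chem.MolFromSmiles(scaffold.smiles)
        if core is None:
            raise ValueError(f"unparseable scaffold {scaffold.smiles!r}")
        for _ in range(scaffold.multiplicity):
            attachments: list[tuple[int, Substituent]] = []
            mol = None
            if scaffold.decorate and spec.substituent_pool:
                for _retry in range(5):
                    positions = _attachable_positions(core)
                    k = int(rng.integers(lo, hi + 1))
                    k = min(k, len(positions))
                    chosen = rng.choice(len(positions), size=k, replace=False) if k else []
                    plan = []
                    ok = True
                    for pi in chosen:
                        pos = positions[int(pi)]
                        allowed = [
                            s for s in spec.substituent_pool
                            if not (s.carbon_only and core.GetAtomWithIdx(pos).GetAtomicNum() != 6)
                        ]
                        if not allowed:
                            ok = False
                            break
                        plan.append((pos, allowed[int(rng.integers(len(allowed)))]))
                    if not ok:
                        continue
                    em = Chem.RWMol(core)
                    for pos, sub in plan:
                        _attach(em, pos, Chem.MolFromSmiles(sub.smiles))
                    try:
                        candidate = em.GetMol()
                        Chem.SanitizeMol(candidate)
                    except Exception:
                        continue
                    mol, attachments = candidate, plan
                    break
            if mol is None:
                mol = Chem.Mol(core)
            smiles = Chem.MolToSmiles(mol)
            records.append(
                MoleculeRecord(
                    id=f"synth{counter:05d}",
                    name=f"{scaffold.smiles}#{counter}",
                    smiles_input=smiles,
                    smiles_std=smiles,
                    inchikey=Chem.MolToInchiKey(mol),
                    dataset_label=DatasetLabel.OTHER,
                )
            )
            counter += 1

            # --- planted truth, from the construction plan ---
            bm = _expected_bm(core, attachments)
            truth.expected_bm_counts[bm] = truth.expected_bm_counts.get(bm, 0) + 1
            if scaffold.is_macrocycle:
                truth.expected_macrocycles += 1
            if scaffold.n_rings == 2:
                n_bicycle_bearing += 1
                ukey = scaffold.unpositioned_key()
                pkey = _positioned_key(core, attachments)
                truth.expected_bicycle_counts_unpositioned[ukey] = (
                    truth.expected_bicycle_counts_unpositioned.get(ukey, 0) + 1
                )
                truth.expected_bicycle_counts_positioned[pkey] = (
                    truth.expected_bicycle_counts_positioned.get(pkey, 0) + 1
                )
            # ring-bearing substituents add monocyclic systems; none are bicycles
            vclass = _violation_class(mol)
            truth.expected_violation_distribution[vclass] = (
                truth.expected_violation_distribution.get(vclass, 0) + 1
            )
    truth.expected_bicycle_prevalence = n_bicycle_bearing / len(records)
    return records, truth


def generate_descriptor_table(
    n: int,
    means: Sequence[float],
    sds: Sequence[float],
    correlation: np.ndarray,
    seed: int = 0,
    names: Optional[Sequence[str]] = None,
):
    """Multivariate-normal descriptor table with requested moments.

    ``correlation`` must be positive semi-definite; columns with zero SD
    come out exactly constant.
    """
    import pandas as pd

    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    correlation = np.asarray(correlation, dtype=float)
    p = len(means)
    if sds.shape != (p,) or correlation.shape != (p, p):
        raise ValueError("means, sds and correlation have inconsistent shapes")
    eigvals = np.linalg.eigvalsh(correlation)
    if eigvals.min() < -1e-10:
        raise ValueError("correlation matrix is not positive semi-definite")
    cov = correlation * np.outer(sds, sds)
    rng = np.random.default_rng(seed)
    X = rng.multivariate_normal(means, cov, size=n, method="svd")
    X[:, sds == 0] = means[sds == 0]
    if names is None:
        names = [f"var{i + 1}" for i in range(p)]
    return pd.DataFrame(X, columns=list(names))
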