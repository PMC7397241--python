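"""Physicochemical descriptor panel, rule-of-five/Veber profiling, and
mean ± k·SD guideline ranges.

The panel is the 12-descriptor set used throughout the analysis: MW,
Wildman–Crippen ClogP, TPSA, HBA/HBD in the Lipinski N+O / NH+OH counting
convention, rotatable bonds, heavy atoms, aromatic rings, chiral atoms
(potential tetrahedral stereocenters, assigned or not), Fsp3, and MQN
components 8 and 10 of the 42-component Molecular Quantum Numbers vector.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors, Lipinski, rdMolDescriptors

from .chemio import MoleculeRecord

__all__ = [
    "DescriptorVector",
    "RuleProfile",
    "GuidelineRange",
    "compute_descriptors",
    "descriptor_frame",
    "rule_profile",
    "violation_distribution",
    "derive_guidelines",
    "guideline_from_values",
    "COUNT_DESCRIPTORS",
    "DESCRIPTOR_ORDER",
]

#: Column order used for tabular output: the distribution-grid panels
#: (HBA..NCA) followed by MQN8, MQN10, FCSP3.
DESCRIPTOR_ORDER = [
    "HBA", "HBD", "ClogP", "MW", "NHA", "NRB", "TPSA", "NAR", "NCA",
    "MQN8", "MQN10", "FCSP3",
]

#: Descriptors that are integer counts; their guideline lower bounds are
#: clamped at zero and their presentation form is rounded to integers.
COUNT_DESCRIPTORS = {"HBA", "HBD", "NRB", "NHA", "NAR", "NCA", "MQN8", "MQN10"}


@dataclass
class DescriptorVector:
    MW: float
    ClogP: float
    TPSA: float
    HBA: int
    HBD: int
    NRB: int
    NHA: int
    NAR: int
    NCA: int
    FCSP3: float
    MQN8: int
    MQN10: int

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class RuleProfile:
    lipinski_flags: dict  # {"MW": bool, "ClogP": bool, "HBA": bool, "HBD": bool}
    lipinski_violations: int
    veber_flags: dict  # {"TPSA": bool, "NRB": bool}
    veber_violations: int


@dataclass
class GuidelineRange:
    descriptor: str
    mean: float
    sd: float
    lower: float
    upper: float

    def rounded(self) -> tuple[float, float]:
        """Presentation form: integer bounds for count descriptors."""
        if self.descriptor in COUNT_DESCRIPTORS:
            return float(round(self.lower)), float(round(self.upper))
        return round(self.lower, 1), round(self.upper, 1)


def compute_descriptors(record: "MoleculeRecord | Chem.Mol | str") -> DescriptorVector:
    """Compute the 12-descriptor panel for one standardized structure."""
    if isinstance(record, MoleculeRecord):
        mol = record.to_mol()
    elif isinstance(record, str):
        mol = Chem.MolFromSmiles(record)
    else:
        mol = record
    if mol is None:
        raise ValueError("invalid structure; standardization should have caught this")
    mqn = rdMolDescriptors.MQNs_(mol)
    n_chiral = len(
        Chem.FindMolChiralCenters(mol, includeUnassigned=True, useLegacyImplementation=False)
    )
    return DescriptorVector(
        MW=Descriptors.MolWt(mol),
        ClogP=Descriptors.MolLogP(mol),
        TPSA=Descriptors.TPSA(mol),
        HBA=Lipinski.NOCount(mol),
        HBD=Lipinski.NHOHCount(mol),
        NRB=Lipinski.NumRotatableBonds(mol),
        NHA=mol.GetNumHeavyAtoms(),
        NAR=rdMolDescriptors.CalcNumAromaticRings(mol),
        NCA=n_chiral,
        FCSP3=Descriptors.FractionCSP3(mol),
        MQN8=int(mqn[7]),
        MQN10=int(mqn[9]),
    )


def descriptor_frame(records: Sequence[MoleculeRecord]) -> pd.DataFrame:
    """Descriptor table (one row per molecule, id-indexed, fixed column order)."""
    rows = {r.id: compute_descriptors(r).as_dict() for r in records}
    return pd.DataFrame.from_dict(rows, orient="index")[DESCRIPTOR_ORDER]


# Rule-of-five and Veber limits; a violation is a strict exceedance, so a
# value exactly at the limit is compliant.
LIPINSKI_LIMITS = {"MW": 500.0, "ClogP": 5.0, "HBA": 10, "HBD": 5}
VEBER_LIMITS = {"TPSA": 140.0, "NRB": 10}


def rule_profile(d: DescriptorVector) -> RuleProfile:
    lip = {k: getattr(d, k) > v for k, v in LIPINSKI_LIMITS.items()}
    veb = {k: getattr(d, k) > v for k, v in VEBER_LIMITS.items()}
    return RuleProfile(
        lipinski_flags=lip,
        lipinski_violations=sum(lip.values()),
        veber_flags=veb,
        veber_violations=sum(veb.values()),
    )


VIOLATION_CLASSES = ["0", "1", "2", ">2"]


def violation_distribution(vectors: Sequence[DescriptorVector]) -> pd.DataFrame:
    """Tabulate molecules by number of rule-of-five violations (0, 1, 2, >2)."""
    if len(vectors) == 0:
        raise ValueError("violation_distribution requires a non-empty descriptor list")
    counts = {c: 0 for c in VIOLATION_CLASSES}
    for d in vectors:
        v = rule_profile(d).lipinski_violations
        counts[str(v) if v <= 2 else ">2"] += 1
    n = len(vectors)
    return pd.DataFrame(
        {
            "violations": VIOLATION_CLASSES,
            "count": [counts[c] for c in VIOLATION_CLASSES],
            "percent": [100.0 * counts[c] / n for c in VIOLATION_CLASSES],
        }
    )


def guideline_from_values(
    descriptor: str, values: Sequence[float], k_sd: float = 2.0,
    clamp_zero: Optional[bool] = None,
) -> GuidelineRange:
    """Mean ± k·SD range for one descriptor column (sample SD, n−1).

    The default two-SD band corresponds to a 95.4% interval under
    normality.  Count descriptors have their lower bound clamped at zero.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("guideline derivation needs at least two observations")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    lower, upper = mean - k_sd * sd, mean + k_sd * sd
    if clamp_zero is None:
        clamp_zero = descriptor in COUNT_DESCRIPTORS
    if clamp_zero:
        lower = max(lower, 0.0)
    return GuidelineRange(descriptor=descriptor, mean=mean, sd=sd, lower=lower, upper=upper)


def derive_guidelines(
    vectors: "Sequence[DescriptorVector] | pd.DataFrame", k_sd: float = 2.0
) -> list[GuidelineRange]:
    """Guideline ranges for every descriptor in the panel."""
    if isinstance(vectors, pd.DataFrame):
        frame = vectors
    else:
        frame = pd.DataFrame([v.as_dict() for v in vectors])
    return [guideline_from_values(col, frame[col].to_numpy(), k_sd) for col in frame.columns]


def guidelines_frame(guidelines: Sequence[GuidelineRange]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "descriptor": g.descriptor,
                "mean": g.mean,
                "sd": g.sd,
                "lower": g.lower,
                "upper": g.upper,
                "lower_rounded": g.rounded()[0],
                "upper_rounded": g.rounded()[1],
            }
            for g in guidelines
        ]
    )
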