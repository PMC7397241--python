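"""Reading, standardizing, deduplicating and writing molecule sets.

Standardization keeps the largest organic fragment (dropping counter-ions
such as bromide), neutralizes formal charges where a neutral form exists,
and picks one canonical tautomer deterministically.  Identity for
deduplication is the standard InChIKey of the standardized structure, so
stereoisomers — distinct drugs — are kept apart.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.warning")

__all__ = [
    "DatasetLabel",
    "MoleculeRecord",
    "StandardizationReport",
    "read_molecules",
    "standardize",
    "deduplicate",
    "standardize_library",
    "write_records",
    "read_records",
]


class DatasetLabel(str, Enum):
    """Provenance class of a molecule set."""

    APPROVED_PKI = "APPROVED_PKI"
    CLINICAL_PKI = "CLINICAL_PKI"
    CHEMBL_PKI = "CHEMBL_PKI"
    OTHER = "OTHER"


@dataclass
class MoleculeRecord:
    """A single molecule with identity, provenance and standardized form."""

    id: str
    smiles_input: str
    name: str = ""
    smiles_std: str = ""
    inchikey: str = ""
    dataset_label: DatasetLabel = DatasetLabel.OTHER
    phase: Optional[int] = None
    is_valid: bool = True
    counterion_removed: bool = field(default=False, repr=False)

    def to_mol(self) -> Optional[Chem.Mol]:
        """RDKit molecule of the standardized form (input form as fallback)."""
        smi = self.smiles_std or self.smiles_input
        return Chem.MolFromSmiles(smi)


@dataclass
class StandardizationReport:
    n_input: int = 0
    n_counterions_removed: int = 0
    n_empty_or_unparseable: int = 0
    n_duplicates_removed: int = 0
    n_output: int = 0

    def check(self) -> None:
        assert self.n_output == (
            self.n_input - self.n_empty_or_unparseable - self.n_duplicates_removed
        )
        assert min(
            self.n_input,
            self.n_counterions_removed,
            self.n_empty_or_unparseable,
            self.n_duplicates_removed,
            self.n_output,
        ) >= 0


# One module-level set of standardizer objects; construction is expensive.
# Tautomer canonicalization must keep stereocenters: molecules differing
# only in stereochemistry are distinct entities here.
_LARGEST_FRAGMENT = rdMolStandardize.LargestFragmentChooser(preferOrganic=True)
_UNCHARGER = rdMolStandardize.Uncharger()
_TAUTOMER_PARAMS = rdMolStandardize.CleanupParameters()
_TAUTOMER_PARAMS.tautomerRemoveSp3Stereo = False
_TAUTOMER_PARAMS.tautomerRemoveBondStereo = False
_TAUTOMERS = rdMolStandardize.TautomerEnumerator(_TAUTOMER_PARAMS)


def _coerce_label(value, default: DatasetLabel) -> DatasetLabel:
    if value is None or value == "":
        return default
    if isinstance(value, DatasetLabel):
        return value
    return DatasetLabel(str(value).strip().upper())


def _coerce_phase(value) -> Optional[int]:
    if value is None or value == "":
        return None
    return int(float(value))


def read_molecules(
    path,
    format: str = "smi",
    *,
    smiles_col: str = "smiles",
    name_col: Optional[str] = None,
    label_col: Optional[str] = None,
    phase_col: Optional[str] = None,
    default_label: DatasetLabel = DatasetLabel.OTHER,
    id_prefix: str = "mol",
) -> tuple[list[MoleculeRecord], int]:
    """Read a molecule set from .smi, SDF or CSV.

    Returns ``(records, n_skipped)`` where ``n_skipped`` counts empty or
    unparseable entries; these are logged, never fatal.  Input order is
    preserved and every parseable entry yields exactly one record.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[MoleculeRecord] = []
    n_skipped = 0

    def _add(smiles: str, name: str, label, phase, index: int) -> None:
        nonlocal n_skipped
        smiles = (smiles or "").strip()
        if not smiles or Chem.MolFromSmiles(smiles) is None:
            n_skipped += 1
            logger.warning("skipping entry %d: empty or unparseable SMILES %r", index, smiles)
            return
        records.append(
            MoleculeRecord(
                id=f"{id_prefix}{index:05d}",
                smiles_input=smiles,
                name=name or "",
                dataset_label=_coerce_label(label, default_label),
                phase=_coerce_phase(phase),
            )
        )

    if format == "smi":
        with open(path) as fh:
            for i, line in enumerate(fh):
                line = line.strip()
                if not line:
                    continue
                parts = line.split(None, 1)
                _add(parts[0], parts[1] if len(parts) > 1 else "", None, None, i)
    elif format == "sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                n_skipped += 1
                logger.warning("skipping SDF record %d: unparseable", i)
                continue
            name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
            _add(Chem.MolToSmiles(mol), name, None, None, i)
    elif format == "csv":
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or smiles_col not in reader.fieldnames:
                raise ValueError(f"CSV is missing the declared SMILES column {smiles_col!r}")
            for col in (name_col, label_col, phase_col):
                if col is not None and col not in reader.fieldnames:
                    raise ValueError(f"CSV is missing the declared column {col!r}")
            for i, row in enumerate(reader):
                _add(
                    row.get(smiles_col, ""),
                    row.get(name_col, "") if name_col else "",
                    row.get(label_col) if label_col else None,
                    row.get(phase_col) if phase_col else None,
                    i,
                )
    else:
        raise ValueError(f"unknown format {format!r}; expected smi, sdf or csv")
    return records, n_skipped


def standardize(record: MoleculeRecord) -> MoleculeRecord:
    """Standardize one record: largest organic fragment, neutralized, canonical tautomer.

    Idempotent: standardizing an already-standardized record is a no-op.
    A record whose structure cannot be standardized (e.g., a pure salt with
    no organic fragment) is returned flagged invalid.
    """
    mol = Chem.MolFromSmiles(record.smiles_input)
    if mol is None:
        return replace(record, is_valid=False)
    n_frags_before = len(Chem.GetMolFrags(mol))
    try:
        mol = _LARGEST_FRAGMENT.choose(mol)
        mol = _UNCHARGER.uncharge(mol)
        mol = _TAUTOMERS.Canonicalize(mol)
    except Exception:  # pragma: no cover - rare sanitization corner cases
        logger.warning("standardization failed for %s", record.id)
        return replace(record, is_valid=False)
    if mol is None or mol.GetNumAtoms() == 0:
        return replace(record, is_valid=False)
    smiles_std = Chem.MolToSmiles(mol)
    inchikey = Chem.MolToInchiKey(mol)
    return replace(
        record,
        smiles_std=smiles_std,
        inchikey=inchikey,
        is_valid=True,
        counterion_removed=n_frags_before > 1,
    )


def deduplicate(
    records: Sequence[MoleculeRecord],
    n_skipped_upstream: int = 0,
) -> tuple[list[MoleculeRecord], StandardizationReport]:
    """Drop repeated InChIKeys, keeping the first occurrence of each.

    ``n_skipped_upstream`` folds read-stage unparseable counts into the
    report so that its bookkeeping covers the whole ingestion.
    """
    report = StandardizationReport(n_input=len(records) + n_skipped_upstream)
    report.n_empty_or_unparseable = n_skipped_upstream
    seen: set[str] = set()
    out: list[MoleculeRecord] = []
    for rec in records:
        if not rec.is_valid or not rec.inchikey:
            report.n_empty_or_unparseable += 1
            continue
        if rec.counterion_removed:
            report.n_counterions_removed += 1
        if rec.inchikey in seen:
            report.n_duplicates_removed += 1
            continue
        seen.add(rec.inchikey)
        out.append(rec)
    report.n_output = len(out)
    report.check()
    return out, report


def standardize_library(
    records: Iterable[MoleculeRecord],
    n_skipped_upstream: int = 0,
) -> tuple[list[MoleculeRecord], StandardizationReport]:
    """Standardize then deduplicate a whole set; the usual ingestion path."""
    standardized = [standardize(r) for r in records]
    return deduplicate(standardized, n_skipped_upstream)


_CSV_COLUMNS = ["id", "name", "smiles_std", "inchikey", "dataset_label", "phase"]


def write_records(records: Sequence[MoleculeRecord], path) -> None:
    """Write records as CSV with the fixed column order."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_COLUMNS)
        for r in records:
            writer.writerow(
                [r.id, r.name, r.smiles_std, r.inchikey, r.dataset_label.value,
                 "" if r.phase is None else r.phase]
            )


def read_records(path) -> list[MoleculeRecord]:
    """Read back a CSV written by :func:`write_records`."""
    out = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out.append(
                MoleculeRecord(
                    id=row["id"],
                    name=row["name"],
                    smiles_input=row["smiles_std"],
                    smiles_std=row["smiles_std"],
                    inchikey=row["inchikey"],
                    dataset_label=DatasetLabel(row["dataset_label"]),
                    phase=_coerce_phase(row["phase"]),
                )
            )
    return out
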