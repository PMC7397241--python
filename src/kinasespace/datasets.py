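"""Building a kinase-active compound set from a bioactivity table.

A molecule qualifies when at least one of its activity rows is a kinase
IC50/Ki/Kd measurement with pChEMBL strictly above the threshold
(pChEMBL > 6 is sub-micromolar potency).  Qualifying molecules are
standardized, deduplicated, and filtered against an exclusion list of
InChIKeys (the clinical/approved set under comparison).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from typing import Optional, Sequence

from .chemio import (
    DatasetLabel,
    MoleculeRecord,
    StandardizationReport,
    standardize_library,
)

logger = logging.getLogger(__name__)

__all__ = ["ActivityRow", "read_activity_csv", "build_pki_set", "assemble_comparison"]

QUALIFYING_ACTIVITY_TYPES = {"IC50", "KI", "KD"}


@dataclass
class ActivityRow:
    smiles: str
    target_id: str
    target_is_kinase: bool
    activity_type: str  # IC50 | Ki | Kd | other
    pchembl: Optional[float]  # -log10 molar


def _parse_bool(value) -> bool:
    return str(value).strip().lower() in ("1", "true", "yes", "y")


def read_activity_csv(path) -> list[ActivityRow]:
    """Read an activity table (columns: smiles, target_id, target_is_kinase,
    activity_type, pchembl).  Malformed rows are logged and skipped."""
    rows = []
    with open(path, newline="", encoding="utf-8") as fh:
        for i, row in enumerate(csv.DictReader(fh)):
            try:
                raw = (row.get("pchembl") or "").strip()
                rows.append(
                    ActivityRow(
                        smiles=row["smiles"].strip(),
                        target_id=row.get("target_id", "").strip(),
                        target_is_kinase=_parse_bool(row.get("target_is_kinase", "")),
                        activity_type=row.get("activity_type", "").strip(),
                        pchembl=float(raw) if raw else None,
                    )
                )
            except (KeyError, ValueError) as exc:
                logger.warning("skipping malformed activity row %d: %s", i, exc)
    return rows


def build_pki_set(
    rows: Sequence[ActivityRow],
    exclusion: "set[str] | Sequence[str]" = (),
    pchembl_min: float = 6.0,
) -> tuple[list[MoleculeRecord], StandardizationReport]:
    """Select, standardize and deduplicate kinase-active molecules.

    The pChEMBL threshold is strict (a value exactly at the threshold is
    excluded).  ``exclusion`` is a set of InChIKeys removed after
    standardization.
    """
    qualifying: list[str] = []
    seen: set[str] = set()
    for row in rows:
        if not row.target_is_kinase:
            continue
        if row.activity_type.upper() not in QUALIFYING_ACTIVITY_TYPES:
            continue
        if row.pchembl is None or not row.pchembl > pchembl_min:
            continue
        if not row.smiles:
            continue
        if row.smiles not in seen:  # cheap pre-dedup; real identity is by InChIKey
            seen.add(row.smiles)
            qualifying.append(row.smiles)
    records = [
        MoleculeRecord(id=f"chembl{i:05d}", smiles_input=smi,
                       dataset_label=DatasetLabel.CHEMBL_PKI)
        for i, smi in enumerate(qualifying)
    ]
    records, report = standardize_library(records)
    exclusion = set(exclusion)
    kept = [r for r in records if r.inchikey not in exclusion]
    n_excluded = len(records) - len(kept)
    report.n_duplicates_removed += n_excluded
    report.n_output = len(kept)
    report.check()
    return kept, report


def assemble_comparison(
    sets: Sequence[Sequence[MoleculeRecord]],
) -> tuple[list[MoleculeRecord], dict[str, list[str]]]:
    """Merge labeled record sets, reporting InChIKeys seen in several sets.

    On a label conflict the first set wins (with a warning); the overlap
    report maps each shared InChIKey to the labels that claimed it.
    """
    merged: list[MoleculeRecord] = []
    first_label: dict[str, str] = {}
    overlap: dict[str, list[str]] = {}
    for records in sets:
        for rec in records:
            label = rec.dataset_label.value
            if rec.inchikey in first_label:
                overlap.setdefault(rec.inchikey, [first_label[rec.inchikey]]).append(label)
                if label != first_label[rec.inchikey]:
                    logger.warning(
                        "conflicting labels for %s: keeping %s, ignoring %s",
                        rec.inchikey, first_label[rec.inchikey], label,
                    )
                continue
            first_label[rec.inchikey] = label
            merged.append(rec)
    return merged, overlap
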