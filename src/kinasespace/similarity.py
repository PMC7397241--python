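"""Pairwise structural similarity statistics and Butina clustering.

Two fingerprint kinds are supported: 166-bit structural keys (MACCS) for
the diversity statistics, and circular radius-2 (Morgan) fingerprints for
clustering.  Pair statistics stream over the n(n−1)/2 unordered pairs
with a Welford accumulator, so no full similarity matrix is retained,
while reproducing the exact two-pass result.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt
from typing import Sequence

from rdkit import Chem, DataStructs
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator
from rdkit.ML.Cluster import Butina

from .chemio import MoleculeRecord

__all__ = ["SimilarityStats", "pairwise_similarity", "cluster_butina", "FINGERPRINT_KINDS"]

FINGERPRINT_KINDS = ("structural_keys_166", "circular_radius2")

_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


@dataclass
class SimilarityStats:
    n_pairs: int
    mean: float
    sd: float
    fingerprint_kind: str


def _fingerprints(records: Sequence[MoleculeRecord], kind: str):
    if kind not in FINGERPRINT_KINDS:
        raise ValueError(f"unknown fingerprint kind {kind!r}")
    fps = []
    for rec in records:
        mol = rec.to_mol() if isinstance(rec, MoleculeRecord) else Chem.MolFromSmiles(rec)
        if mol is None:
            raise ValueError(f"invalid structure in similarity input: {rec!r}")
        fps.append(
            MACCSkeys.GenMACCSKeys(mol)
            if kind == "structural_keys_166"
            else _MORGAN.GetFingerprint(mol)
        )
    return fps


def pairwise_similarity(
    records: Sequence[MoleculeRecord], fingerprint_kind: str = "structural_keys_166"
) -> SimilarityStats:
    """Mean and sample SD of Tanimoto similarity over all unordered pairs."""
    n = len(records)
    if n < 2:
        raise ValueError("pairwise similarity needs at least two molecules")
    fps = _fingerprints(records, fingerprint_kind)
    # Welford over the pair stream
    count = 0
    mean = 0.0
    m2 = 0.0
    for i in range(1, n):
        sims = DataStructs.BulkTanimotoSimilarity(fps[i], fps[:i])
        for s in sims:
            count += 1
            delta = s - mean
            mean += delta / count
            m2 += delta * (s - mean)
    sd = sqrt(m2 / (count - 1)) if count > 1 else 0.0
    return SimilarityStats(n_pairs=count, mean=mean, sd=sd, fingerprint_kind=fingerprint_kind)


def cluster_butina(
    records: Sequence[MoleculeRecord], threshold: float = 0.6
) -> list[tuple[int, ...]]:
    """Butina leader clustering at a Tanimoto-distance threshold.

    Uses circular radius-2 fingerprints.  Returns clusters as tuples of
    input indices; the first index of each cluster is its centroid.  The
    assignment depends on input order, which is the algorithm's documented
    behavior.
    """
    n = len(records)
    if n == 0:
        raise ValueError("cluster_butina needs at least one molecule")
    if n == 1:
        return [(0,)]
    fps = _fingerprints(records, "circular_radius2")
    dists = []
    for i in range(1, n):
        sims = DataStructs.BulkTanimotoSimilarity(fps[i], fps[:i])
        dists.extend(1.0 - s for s in sims)
    clusters = Butina.ClusterData(dists, n, threshold, isDistData=True)
    return [tuple(c) for c in clusters]
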