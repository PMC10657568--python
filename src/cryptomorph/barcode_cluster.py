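"""DNA-barcode objective clustering on uncorrected p-distances.

Aligned barcode sequences are compared by the uncorrected p-distance: the
proportion of differing sites among sites where both sequences carry an
unambiguous base (A/C/G/T).  Sites with N, gaps, or other ambiguity codes
in either sequence are excluded from numerator and denominator (pairwise
deletion).  Objective clustering then groups sequences into the connected
components of the graph joining pairs within a distance threshold — the
single-linkage cut — and the full single-linkage merge profile gives the
thresholds at which putative species units coalesce (the dendrogram
published alongside such analyses).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform

from .io_formats import DatasetError, SequenceSet

__all__ = [
    "DistanceMatrix",
    "ClusterPartition",
    "MergeProfile",
    "p_distance_matrix",
    "objective_cluster",
    "merge_profile",
]

_UNAMBIGUOUS = frozenset(b"ACGT")


@dataclass
class DistanceMatrix:
    """Symmetric uncorrected p-distance matrix with comparable-site counts."""

    ids: list[str]
    matrix: np.ndarray  # (n, n) in [0, 1]; NaN where no comparable sites
    comparable: np.ndarray  # (n, n) int site counts

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def has_missing(self) -> bool:
        off = ~np.eye(self.n, dtype=bool)
        return bool(np.isnan(self.matrix[off]).any())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.ids, columns=self.ids)

    def to_phylip(self) -> str:
        lines = [f"{self.n}"]
        for i, sid in enumerate(self.ids):
            vals = " ".join(f"{v:.6f}" for v in self.matrix[i])
            lines.append(f"{sid:<12s}{vals}")
        return "\n".join(lines) + "\n"


@dataclass
class ClusterPartition:
    """Threshold clustering: connected components at one distance cutoff."""

    threshold: float
    assignment: dict  # id -> cluster index (0-based, order of first member)
    n_clusters: int

    def members(self) -> dict:
        out: dict[int, list[str]] = {}
        for sid, c in self.assignment.items():
            out.setdefault(c, []).append(sid)
        return out

    def labels(self, ids: list[str]) -> np.ndarray:
        return np.array([self.assignment[i] for i in ids])


@dataclass
class MergeProfile:
    """Single-linkage agglomeration history (heights non-decreasing)."""

    ids: list[str]
    linkage_matrix: np.ndarray  # scipy (n-1, 4) linkage encoding
    events: list = field(default_factory=list)  # (height, frozenset, frozenset)

    def cut(self, height: float) -> ClusterPartition:
        """Partition at a height; equals objective clustering at that threshold."""
        n = len(self.ids)
        parent = list(range(2 * n - 1))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i, (a, b, h, _) in enumerate(self.linkage_matrix):
            if h <= height + 1e-15:
                parent[find(int(a))] = parent[find(int(b))] = find(n + i)
        roots: dict[int, int] = {}
        assignment: dict[str, int] = {}
        for i, sid in enumerate(self.ids):
            r = find(i)
            if r not in roots:
                roots[r] = len(roots)
            assignment[sid] = roots[r]
        return ClusterPartition(
            threshold=height, assignment=assignment, n_clusters=len(roots)
        )

    def to_newick(self, percent: bool = False) -> str:
        """Dendrogram as Newick with branch lengths from merge heights."""
        n = len(self.ids)
        scale = 100.0 if percent else 1.0
        heights = np.concatenate([np.zeros(n), self.linkage_matrix[:, 2] * scale])
        reps: dict[int, str] = {}
        for i, sid in enumerate(self.ids):
            reps[i] = sid
        for i, (a, b, h, _) in enumerate(self.linkage_matrix):
            a, b = int(a), int(b)
            la = heights[n + i] - heights[a]
            lb = heights[n + i] - heights[b]
            reps[n + i] = f"({reps[a]}:{la:.6g},{reps[b]}:{lb:.6g})"
        return reps[2 * n - 2] + ";"

    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2].copy()


def p_distance_matrix(seqs: SequenceSet) -> DistanceMatrix:
    """Uncorrected p-distances with pairwise deletion of ambiguous sites.

    Only sites where both sequences carry an unambiguous A/C/G/T count;
    pairs sharing no comparable site get a flagged (NaN) distance.
    """
    arr = seqs.as_array()
    n = seqs.n
    valid = np.isin(arr, np.frombuffer(b"ACGT", dtype=np.uint8))
    matrix = np.zeros((n, n))
    comparable = np.zeros((n, n), dtype=int)
    for i in range(n):
        both = valid[i] & valid[i + 1 :]
        diff = (arr[i] != arr[i + 1 :]) & both
        denom = both.sum(axis=1)
        num = diff.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(denom > 0, num / np.maximum(denom, 1), np.nan)
        matrix[i, i + 1 :] = d
        matrix[i + 1 :, i] = d
        comparable[i, i + 1 :] = denom
        comparable[i + 1 :, i] = denom
        comparable[i, i] = int(valid[i].sum())
    return DistanceMatrix(ids=list(seqs.ids), matrix=matrix, comparable=comparable)


def objective_cluster(dist: DistanceMatrix, threshold: float) -> ClusterPartition:
    """Connected components of the graph joining pairs with d <= threshold.

    Equivalent to cutting the single-linkage dendrogram at the threshold.
    Missing (NaN) distances contribute no edge (a warning is emitted).
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside [0, 1]")
    n = dist.n
    if dist.has_missing:
        warnings.warn(
            "distance matrix has missing pairs; treated as above threshold",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore"):
        adj = (dist.matrix <= threshold) & ~np.isnan(dist.matrix)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    # relabel clusters by order of first appearance
    remap: dict[int, int] = {}
    assignment: dict[str, int] = {}
    for sid, lab in zip(dist.ids, labels):
        if lab not in remap:
            remap[lab] = len(remap)
        assignment[sid] = remap[lab]
    return ClusterPartition(threshold=threshold, assignment=assignment, n_clusters=n_comp)


def merge_profile(dist: DistanceMatrix) -> MergeProfile:
    """Single-linkage agglomerative hierarchy of the distance matrix.

    Node heights are the minimum inter-cluster distances at merging;
    cutting the profile at any height reproduces the threshold clustering.
    Requires a complete matrix and n >= 2.
    """
    if dist.n < 2:
        raise DatasetError("merge profile needs at least 2 sequences")
    if dist.has_missing:
        raise DatasetError("merge profile requires a complete distance matrix")
    condensed = squareform(dist.matrix, checks=False)
    Z = linkage(condensed, method="single")
    events = []
    n = dist.n
    members: dict[int, frozenset] = {i: frozenset([sid]) for i, sid in enumerate(dist.ids)}
    for i, (a, b, h, _) in enumerate(Z):
        ma, mb = members[int(a)], members[int(b)]
        events.append((float(h), ma, mb))
        members[n + i] = ma | mb
    return MergeProfile(ids=list(dist.ids), linkage_matrix=Z, events=events)
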