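"""Isomorphism clustering of unit cells and LCV/aLCV annotation.

Crystals whose cell parameters barely differ can be treated as isomorphous
and their data merged.  Datasets are clustered agglomeratively (Ward linkage,
Euclidean metric) on the six cell parameters, each component standardised to
zero mean / unit variance across the input set.  Every dendrogram node is
annotated with the Linear Cell Variation of its member cells:

* aLCV (Angstrom) — the largest absolute pairwise difference among the three
  face-diagonal lengths over all member pairs;
* LCV (percent)  — the same difference relative to the smaller diagonal of
  the pair.

LCV above ~2 % generally signals non-isomorphism.  The longer diagonal of
each cell face is used (both coincide at 90 degrees, the dominant case); this
convention is isolated in :func:`face_diagonals`.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage

from .reflio import UnitCell, UnmergedDataset

__all__ = [
    "ClusterNode",
    "Dendrogram",
    "face_diagonals",
    "cluster_metrics",
    "build_dendrogram",
    "cut_tree",
    "flag_outliers",
    "write_clusters_file",
]


def face_diagonals(cell: UnitCell) -> tuple[float, float, float]:
    """Longer diagonal of the (a,b,gamma), (b,c,alpha) and (a,c,beta) faces."""

    def diag(p: float, q: float, theta: float) -> float:
        return math.sqrt(p * p + q * q + 2 * p * q * abs(math.cos(math.radians(theta))))

    return (
        diag(cell.a, cell.b, cell.gamma),
        diag(cell.b, cell.c, cell.alpha),
        diag(cell.a, cell.c, cell.beta),
    )


def cluster_metrics(cells: Sequence[UnitCell]) -> tuple[float, float]:
    """(LCV %, aLCV Angstrom) over all pairs of cells; (0, 0) for < 2 cells."""
    if len(cells) < 2:
        return 0.0, 0.0
    diags = np.array([face_diagonals(c) for c in cells])  # (n, 3)
    lcv = alcv = 0.0
    for f in range(3):
        col = diags[:, f]
        hi = col.max()
        lo = col.min()
        # the max |d_i - d_j| and max relative difference are both attained
        # by the extreme pair within a face
        alcv = max(alcv, hi - lo)
        lcv = max(lcv, 100.0 * (hi - lo) / lo)
    return float(lcv), float(alcv)


@dataclass
class ClusterNode:
    """Internal dendrogram node.

    ``node_id`` runs n+1 .. 2n-1 above the n leaf serials, in merge order.
    ``children`` holds node_ids/serials; leaves are identified by id <= n.
    ``merge_level`` = member count - 1, so nodes with equal numbers of
    datasets share a level in the merging-level layout.
    """

    node_id: int
    members: frozenset[int]
    height: float
    lcv: float
    alcv: float
    children: tuple[int, int]
    merge_level: int


@dataclass
class Dendrogram:
    """Annotated agglomerative clustering of n datasets (n-1 internal nodes)."""

    leaves: list[int]               # dataset serials, in linkage leaf order
    nodes: list[ClusterNode]        # in merge order, node_id ascending
    linkage_matrix: np.ndarray      # scipy (n-1, 4) linkage, for plotting
    cells: dict[int, UnitCell]      # serial -> raw cell

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def root(self) -> ClusterNode:
        return self.nodes[-1]

    def node(self, node_id: int) -> ClusterNode:
        n = self.n_leaves
        if not n + 1 <= node_id <= 2 * n - 1:
            raise KeyError(f"no internal node {node_id}")
        return self.nodes[node_id - n - 1]

    def members_of(self, ident: int) -> frozenset[int]:
        """Member serials of a node_id, or {ident} for a leaf serial."""
        if ident in self.cells:
            return frozenset({ident})
        return self.node(ident).members


def build_dendrogram(datasets: Sequence[UnmergedDataset]) -> Dendrogram:
    """Ward/Euclidean agglomerative clustering on scaled cell parameters.

    Each of the six components is centred and divided by its across-dataset
    mean, i.e. expressed as a fractional deviation (constant components
    contribute 0).  This removes the unit disparity between edges and angles
    without amplifying components that carry nothing but measurement jitter,
    so a genuine cell difference on one edge dominates the metric.  Nodes are
    annotated with LCV/aLCV computed from the raw cells of their members.
    """
    if len(datasets) < 2:
        raise ValueError("clustering needs at least 2 datasets")
    serials = [ds.serial for ds in datasets]
    if len(set(serials)) != len(serials):
        raise ValueError("dataset serials must be unique")
    order = np.argsort(serials)
    datasets = [datasets[i] for i in order]
    serials = [ds.serial for ds in datasets]
    X = np.array([ds.cell.as_tuple() for ds in datasets], dtype=float)
    mu = X.mean(axis=0)
    Z = (X - mu) / mu
    L = linkage(Z, method="ward", metric="euclidean")
    n = len(datasets)
    cells = {s: ds.cell for s, ds in zip(serials, datasets)}
    members_by_index: dict[int, frozenset[int]] = {
        i: frozenset({serials[i]}) for i in range(n)
    }
    nodes: list[ClusterNode] = []
    for i, (ia, ib, height, _count) in enumerate(L):
        ia, ib = int(ia), int(ib)
        mem = members_by_index[ia] | members_by_index[ib]
        members_by_index[n + i] = mem
        lcv, alcv = cluster_metrics([cells[s] for s in sorted(mem)])

        def ident(idx: int) -> int:
            # leaves keep their serial; internal nodes are numbered n+1+merge
            return serials[idx] if idx < n else n + 1 + (idx - n)

        nodes.append(
            ClusterNode(
                node_id=n + 1 + i,
                members=mem,
                height=float(height),
                lcv=lcv,
                alcv=alcv,
                children=(ident(ia), ident(ib)),
                merge_level=len(mem) - 1,
            )
        )
    return Dendrogram(leaves=serials, nodes=nodes, linkage_matrix=L, cells=cells)


def cut_tree(dendro: Dendrogram, mode: str, threshold: float) -> list[ClusterNode]:
    """Nodes admissible under a height or aLCV threshold, sorted by node_id.

    ``mode='height'`` keeps nodes with merge height <= threshold;
    ``mode='alcv'`` keeps nodes with aLCV (Angstrom) <= threshold.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if mode == "height":
        sel = [nd for nd in dendro.nodes if nd.height <= threshold]
    elif mode == "alcv":
        sel = [nd for nd in dendro.nodes if nd.alcv <= threshold]
    else:
        raise ValueError(f"unknown cut mode {mode!r}")
    return sorted(sel, key=lambda nd: nd.node_id)


def flag_outliers(dendro: Dendrogram, lcv_threshold: float = 2.0) -> list[int]:
    """Advisory list of serials whose removal brings the root LCV under threshold.

    Greedy: while the LCV of the remaining cells exceeds the threshold, take
    the face and extreme pair attaining it and drop the pair member whose
    diagonal lies farther from the median of the remaining cells (the one
    that is the outlier rather than the bulk).  The caller edits the input
    list; nothing is deleted automatically.
    """
    remaining = sorted(dendro.cells)
    removed: list[int] = []

    def lcv_of(serials: Iterable[int]) -> float:
        return cluster_metrics([dendro.cells[s] for s in serials])[0]

    while len(remaining) > 1 and lcv_of(remaining) > lcv_threshold:
        diags = np.array([face_diagonals(dendro.cells[s]) for s in remaining])
        rel = (diags.max(axis=0) - diags.min(axis=0)) / diags.min(axis=0)
        f = int(np.argmax(rel))
        med = float(np.median(diags[:, f]))
        lo, hi = int(np.argmin(diags[:, f])), int(np.argmax(diags[:, f]))
        idx = lo if abs(diags[lo, f] - med) > abs(diags[hi, f] - med) else hi
        removed.append(remaining[idx])
        remaining.pop(idx)
    return sorted(removed)


def write_clusters_file(dendro: Dendrogram, path: str | os.PathLike) -> None:
    """Write CLUSTERS.txt: node_id, height, LCV, aLCV, member serials per row."""
    with open(path, "w") as fh:
        fh.write("# node_id height lcv alcv members\n")
        for nd in dendro.nodes:
            mem = " ".join(str(s) for s in sorted(nd.members))
            fh.write(f"{nd.node_id} {nd.height:.3f} {nd.lcv:.2f} {nd.alcv:.2f} {mem}\n")
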