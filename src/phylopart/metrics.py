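"""Distances and cluster cuts derived from partition trees.

The rank-based distance between two sequences reflects how early the nested
partition separates them: with L split levels on the deepest root-to-tip
path, a pair first separated at depth r (root split = 1) gets distance
(L - r + 1) / L, so root-separated pairs are maximally distant (1) and
sequences sharing a tip have distance 0.  Cutting a tree into k clusters
replays its first k-1 splits in creation order, mirroring a dendrogram cut
at successively lower heights.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .tree import PartitionNode, PartitionTree

__all__ = [
    "DistanceMatrix",
    "ClusterAssignment",
    "rank_distance_matrix",
    "cut_k_clusters",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric nonnegative pairwise distances over named sequences."""

    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        names = tuple(str(n) for n in self.names)
        vals = np.asarray(self.values, dtype=float)
        n = len(names)
        if vals.shape != (n, n):
            raise ValueError(f"distance matrix shape {vals.shape} != ({n}, {n})")
        if len(set(names)) != n:
            raise ValueError("distance matrix names are not distinct")
        if not np.allclose(vals, vals.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(vals) != 0):
            raise ValueError("distance matrix diagonal is not zero")
        if np.any(vals < 0):
            raise ValueError("distance matrix has negative entries")
        vals = np.ascontiguousarray((vals + vals.T) / 2.0)
        vals.setflags(write=False)
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "values", vals)

    @property
    def n(self) -> int:
        return len(self.names)

    def align(self, names) -> np.ndarray:
        """Values reordered to ``names``; raises if any name is missing."""
        index = {n: i for i, n in enumerate(self.names)}
        missing = [n for n in names if n not in index]
        if missing:
            raise KeyError(f"names missing from distance matrix: {missing}")
        idx = np.array([index[n] for n in names])
        return self.values[np.ix_(idx, idx)]

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.names, columns=self.names).to_csv(
            path
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        if list(df.index) != list(df.columns):
            raise ValueError(f"{path}: row and column labels differ")
        return cls(names=tuple(str(c) for c in df.columns), values=df.to_numpy())


@dataclass(frozen=True)
class ClusterAssignment:
    """A partition of named sequences into k clusters."""

    names: tuple[str, ...]
    cluster_ids: np.ndarray
    k: int

    def __post_init__(self) -> None:
        ids = np.asarray(self.cluster_ids, dtype=int)
        if ids.shape != (len(self.names),):
            raise ValueError("one cluster id per sequence required")
        if np.unique(ids).size != self.k:
            raise ValueError(
                f"{np.unique(ids).size} distinct ids for k={self.k} clusters"
            )
        ids = np.ascontiguousarray(ids)
        ids.setflags(write=False)
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "cluster_ids", ids)

    def align(self, names) -> np.ndarray:
        index = {n: i for i, n in enumerate(self.names)}
        missing = [n for n in names if n not in index]
        if missing:
            raise KeyError(f"names missing from partition: {missing}")
        return self.cluster_ids[np.array([index[n] for n in names])]


def _split_depths(tree: PartitionTree) -> dict[int, int]:
    """Depth (1-based, root split = 1) of each internal node, keyed by id."""
    depths: dict[int, int] = {}
    stack: list[tuple[PartitionNode, int]] = [(tree.root, 0)]
    while stack:
        node, d = stack.pop()
        if not node.is_tip:
            depths[id(node)] = d + 1
            for c in node.children:
                stack.append((c, d + 1))
    return depths


def rank_distance_matrix(tree: PartitionTree) -> DistanceMatrix:
    """Rank-based pairwise distances between sequences of a partition tree.

    Pairs sharing a tip get 0; a pair first separated at split depth r gets
    (L - r + 1) / L where L is the number of internal nodes on the deepest
    root-to-tip path.  A single-tip tree yields the all-zero matrix.
    """
    n = len(tree.hap_names)
    out = np.zeros((n, n))
    depths = _split_depths(tree)
    if depths:
        L = max(depths.values())
        stack = [tree.root]
        while stack:
            node = stack.pop()
            if node.is_tip:
                continue
            d = (L - depths[id(node)] + 1) / L
            left, right = node.children
            li = np.fromiter(left.rows, dtype=np.intp)
            ri = np.fromiter(right.rows, dtype=np.intp)
            out[np.ix_(li, ri)] = d
            out[np.ix_(ri, li)] = d
            stack.extend(node.children)
    return DistanceMatrix(names=tree.hap_names, values=out)


def cut_k_clusters(tree: PartitionTree, k: int) -> ClusterAssignment:
    """Partition into k clusters by applying the first k-1 splits.

    Splits are applied in creation-rank order (the order the recursive
    partitioning performed them); ranks increase down the tree, so the
    clusters after k-1 splits are the leaf-sets of the frontier at which a
    node's rank exceeds k-1.
    """
    n_tips = tree.n_tips
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > n_tips:
        raise ValueError(f"k={k} exceeds the tree's {n_tips} tips")
    ids = np.empty(len(tree.hap_names), dtype=int)
    next_id = 0
    stack = [tree.root]
    clusters: list[PartitionNode] = []
    while stack:
        node = stack.pop(0)
        if node.is_tip or node.rank > k - 1:
            clusters.append(node)
        else:
            stack.extend(node.children)
    for node in clusters:
        for r in node.rows:
            ids[r] = next_id
        next_id += 1
    return ClusterAssignment(names=tree.hap_names, cluster_ids=ids, k=k)
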