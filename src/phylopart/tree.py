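"""Recursive partitioning of sequences into a rooted binary partition tree.

Starting from one cluster holding every sequence, the ordered neighborhood
SNVs are processed once, left to right.  Each SNV splits every active cluster
that is polymorphic at it into the allele-0 subcluster and the allele-1
(derived-allele-carrier) subcluster.  Clusters that can no longer be split
become tips; sequences indistinguishable over the window share a tip whose
label joins their names with a separator.  The result approximates the local
perfect phylogeny around the focal SNV.

Trees carry no branch lengths — the method defines none — so Newick output
is topology-only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .compat import Neighborhood, order_neighborhood, select_neighborhood
from .hapmat import HapMat

__all__ = [
    "PartitionNode",
    "PartitionTree",
    "RegionScan",
    "build_partition",
    "reconstruct_pp",
    "reconstruct_pp_region",
    "to_newick",
    "partition_tree_from_newick",
    "window_report",
]


@dataclass
class PartitionNode:
    """A node of a partition tree.

    A tip has ``children == ()`` and holds its sequence row indices in
    original HapMat order.  An internal node records the splitting SNV and
    its creation rank (1 = first split performed); its first child is the
    allele-0 subcluster, its second the allele-1 (derived) subcluster.
    """

    rows: tuple[int, ...]
    children: tuple["PartitionNode", ...] = ()
    snv_index: int | None = None
    snv_name: str | None = None
    rank: int | None = None

    @property
    def is_tip(self) -> bool:
        return not self.children


@dataclass
class PartitionTree:
    """Rooted binary tree of nested sequence partitions at one focal SNV."""

    root: PartitionNode
    hap_names: tuple[str, ...]
    sep: str = "-"
    focal_index: int | None = None
    focal_name: str | None = None
    lower_pos: float | None = None
    upper_pos: float | None = None
    neighborhood: Neighborhood | None = None
    # internal nodes in creation-rank order (rank i at position i-1)
    splits: list[PartitionNode] = field(default_factory=list)

    def tips(self) -> list[PartitionNode]:
        out: list[PartitionNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.is_tip:
                out.append(node)
            else:
                stack.extend(reversed(node.children))
        return out

    @property
    def n_tips(self) -> int:
        return len(self.tips())

    def tip_label(self, node: PartitionNode) -> str:
        return self.sep.join(self.hap_names[r] for r in node.rows)

    def tip_partition(self) -> list[tuple[str, ...]]:
        """Sequence-name groups of the tips, in left-to-right tree order."""
        return [tuple(self.hap_names[r] for r in t.rows) for t in self.tips()]

    def bipartitions(self) -> set[frozenset[str]]:
        """Leaf-name sets below each non-root node (trivial root side dropped)."""
        out: set[frozenset[str]] = set()
        stack = list(self.root.children)
        while stack:
            node = stack.pop()
            out.add(frozenset(self.hap_names[r] for r in node.rows))
            stack.extend(node.children)
        return out


def build_partition(
    hapmat: HapMat, ordered_snvs, sep: str = "-"
) -> PartitionTree:
    """Recursively partition all sequences on ``ordered_snvs``.

    The SNV list is processed globally in one pass; each SNV splits every
    active polymorphic cluster.  A SNV monomorphic within a cluster is
    skipped for that cluster, so every internal node has exactly two
    children.
    """
    ordered_snvs = list(ordered_snvs)
    if not ordered_snvs:
        raise ValueError("ordered_snvs must be nonempty")
    n = hapmat.n_seq
    root = PartitionNode(rows=tuple(range(n)))
    active = [root]
    splits: list[PartitionNode] = []
    rank = 0
    for j in ordered_snvs:
        col = hapmat.column(j)
        next_active: list[PartitionNode] = []
        for node in active:
            if len(node.rows) > 1:
                rows = np.fromiter(node.rows, dtype=np.intp)
                ones_mask = col[rows] == 1
                if ones_mask.any() and not ones_mask.all():
                    rank += 1
                    zero_child = PartitionNode(rows=tuple(rows[~ones_mask].tolist()))
                    one_child = PartitionNode(rows=tuple(rows[ones_mask].tolist()))
                    node.children = (zero_child, one_child)
                    node.snv_index = int(j)
                    node.snv_name = hapmat.snv_names[j]
                    node.rank = rank
                    splits.append(node)
                    next_active.extend((zero_child, one_child))
                    continue
            next_active.append(node)
        active = next_active
    return PartitionTree(
        root=root, hap_names=hapmat.hap_names, sep=sep, splits=splits
    )


def reconstruct_pp(
    hapmat: HapMat,
    focal_snv: int,
    min_window: int | None = None,
    sep: str = "-",
) -> PartitionTree:
    """Reconstruct the partition tree at one focal SNV (0-based column index).

    Composes neighborhood selection, SNV ordering and recursive partitioning;
    the returned tree records the bp limits of the window used.
    """
    nbhd = select_neighborhood(hapmat, focal_snv, min_window)
    ordered = order_neighborhood(hapmat, nbhd)
    tree = build_partition(hapmat, ordered, sep=sep)
    tree.focal_index = focal_snv
    tree.focal_name = hapmat.snv_names[focal_snv]
    tree.lower_pos = nbhd.lower_pos
    tree.upper_pos = nbhd.upper_pos
    tree.neighborhood = nbhd
    return tree


@dataclass
class RegionScan:
    """Partition trees at each focal SNV scanned across a region."""

    trees: list[PartitionTree]
    focal_indices: tuple[int, ...]
    positions: np.ndarray  # bp of each focal SNV
    snv_names: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)


def reconstruct_pp_region(
    hapmat: HapMat,
    min_window: int | None = None,
    sep: str = "-",
    pos_lower: float | None = None,
    pos_upper: float | None = None,
) -> RegionScan:
    """Reconstruct a partition tree at every focal SNV in a (sub)region.

    ``pos_lower``/``pos_upper`` (bp, inclusive) restrict which SNVs serve as
    focal points; windows may still extend beyond these bounds.
    """
    if pos_lower is not None and pos_upper is not None and pos_lower > pos_upper:
        raise ValueError("pos_lower must not exceed pos_upper")
    pos = hapmat.positions
    mask = np.ones(hapmat.n_snv, dtype=bool)
    if pos_lower is not None:
        mask &= pos >= pos_lower
    if pos_upper is not None:
        mask &= pos <= pos_upper
    focal = np.flatnonzero(mask)
    if focal.size == 0:
        raise ValueError(
            f"no focal SNVs in subregion [{pos_lower}, {pos_upper}] bp"
        )
    trees = [
        reconstruct_pp(hapmat, int(j), min_window=min_window, sep=sep)
        for j in focal
    ]
    return RegionScan(
        trees=trees,
        focal_indices=tuple(int(j) for j in focal),
        positions=pos[focal],
        snv_names=tuple(hapmat.snv_names[int(j)] for j in focal),
    )


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

_NEEDS_QUOTE = set("()[]{}:;,='\" \t\n")


def _newick_label(label: str) -> str:
    if any(c in _NEEDS_QUOTE for c in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(tree: PartitionTree, annotate_snvs: bool = False) -> str:
    """Topology-only Newick string; multi-sequence tips are single leaves.

    A single-tip tree is written as a bare leaf (``a-b;``).  With
    ``annotate_snvs`` the splitting SNV name is attached to each internal
    node as a node label.
    """

    def render(node: PartitionNode) -> str:
        if node.is_tip:
            return _newick_label(tree.tip_label(node))
        inner = ",".join(render(c) for c in node.children)
        label = (
            _newick_label(node.snv_name)
            if annotate_snvs and node.snv_name is not None
            else ""
        )
        return f"({inner}){label}"

    return render(tree.root) + ";"


def partition_tree_from_newick(
    newick: str, sep: str = "-"
) -> PartitionTree:
    """Parse a binary Newick tree into a :class:`PartitionTree`.

    Tip labels may be ``sep``-joined groups of sequence names.  Split
    creation ranks, which a plain Newick string does not carry, are assigned
    breadth-first from the root (depth order, left to right within a depth) —
    the analogue of cutting a dendrogram at successively lower heights.
    """
    import dendropy

    dtree = dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )
    names: list[str] = []

    def convert(dnode) -> PartitionNode:
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon else (dnode.label or "")
            group = tuple(label.split(sep)) if label else ()
            start = len(names)
            names.extend(group)
            return PartitionNode(rows=tuple(range(start, start + len(group))))
        kids = dnode.child_nodes()
        if len(kids) != 2:
            raise ValueError(
                "comparator dendrogram must be strictly binary; "
                f"found a node with {len(kids)} children"
            )
        children = tuple(convert(k) for k in kids)
        rows = tuple(r for c in children for r in c.rows)
        return PartitionNode(rows=rows, children=children)

    root = convert(dtree.seed_node)
    if len(set(names)) != len(names):
        raise ValueError("duplicate sequence names in Newick tips")
    # assign ranks breadth-first
    splits: list[PartitionNode] = []
    queue = [root]
    while queue:
        node = queue.pop(0)
        if not node.is_tip:
            node.rank = len(splits) + 1
            splits.append(node)
            queue.extend(node.children)
    return PartitionTree(
        root=root, hap_names=tuple(names), sep=sep, splits=splits
    )


def window_report(tree: PartitionTree) -> str:
    """Plain-text report of the window behind a reconstructed tree."""
    nb = tree.neighborhood
    lines = [
        f"focal SNV: {tree.focal_name}",
        f"window: {tree.lower_pos:g} - {tree.upper_pos:g} bp",
    ]
    if nb is not None:
        lines.append(
            "compatible (ancient->recent): " + " ".join(nb.compatible_names)
        )
        lines.append(
            "incompatible (by proximity): " + " ".join(nb.incompatible_names)
        )
    return "\n".join(lines)
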