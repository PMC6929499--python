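"""Synthetic haplotype data with known ancestral structure.

The generator emulates infinite-sites haplotypes on a genealogy: a random
rooted binary topology (iterative random pairwise joins, i.e. a Yule-type
process, without waiting times — the reconstruction uses no branch lengths),
mutations dropped uniformly over branches so that each SNV's derived-allele
carriers are exactly one clade, optional recombination breakpoints giving
independent genealogies per segment, and a binary phenotype driven by causal
SNVs within a designated subregion via a logistic model.

Within a non-recombining segment every SNV pair passes the four-gamete test
(carrier sets are nested or disjoint); incompatibilities only arise across
breakpoints, which is what the compatibility windowing must detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .compat import four_gamete_compatible
from .hapmat import HapMat, create_hapmat
from .metrics import DistanceMatrix

__all__ = [
    "GenealogyNode",
    "SimulatedRegion",
    "simulate_genealogy",
    "drop_infinite_sites_mutations",
    "simulate_region_with_recombination",
    "simulate_phenotype",
    "genealogy_to_newick",
    "genealogy_clades",
]


@dataclass
class GenealogyNode:
    """Node of a simulated genealogy: a leaf (named) or a binary join."""

    name: str | None = None
    children: tuple["GenealogyNode", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        return [n for c in self.children for n in c.leaves()]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_genealogy(
    n_seq: int, seed=None, names: list[str] | None = None
) -> GenealogyNode:
    """Random rooted binary topology over ``n_seq`` labelled sequences.

    Built by iterative uniform random pairwise joins of the active lineages
    (every labelled pair is equally likely to be the first join), so the
    topology follows a Yule-type process.  Deterministic given the seed.
    """
    if n_seq < 2:
        raise ValueError("a genealogy needs at least 2 sequences")
    rng = _rng(seed)
    if names is None:
        names = [f"h{i + 1}" for i in range(n_seq)]
    if len(names) != n_seq:
        raise ValueError("one name per sequence required")
    active = [GenealogyNode(name=n) for n in names]
    while len(active) > 1:
        i, j = sorted(rng.choice(len(active), size=2, replace=False).tolist())
        joined = GenealogyNode(children=(active[i], active[j]))
        # remove the later index first to keep positions valid
        del active[j]
        del active[i]
        active.append(joined)
    return active[0]


def _branches(root: GenealogyNode) -> list[GenealogyNode]:
    """All non-root nodes, each standing for the branch above it (preorder)."""
    out: list[GenealogyNode] = []
    stack = list(root.children)
    while stack:
        node = stack.pop()
        out.append(node)
        stack.extend(node.children)
    return out


def genealogy_clades(root: GenealogyNode) -> set[frozenset[str]]:
    """Leaf-name set below each non-root branch of the genealogy."""
    return {frozenset(b.leaves()) for b in _branches(root)}


def genealogy_to_newick(root: GenealogyNode) -> str:
    def render(node: GenealogyNode) -> str:
        if node.is_leaf:
            return node.name
        return "(" + ",".join(render(c) for c in node.children) + ")"

    return render(root) + ";"


def _mutation_columns(
    root: GenealogyNode, n_snv: int, rng: np.random.Generator, row_of: dict[str, int]
) -> np.ndarray:
    """(n_seq, n_snv) 0/1 matrix; each column's carriers are one random clade."""
    branches = _branches(root)
    carrier_rows = [
        np.array([row_of[name] for name in b.leaves()]) for b in branches
    ]
    n = len(row_of)
    matrix = np.zeros((n, n_snv), dtype=np.int8)
    picks = rng.integers(len(branches), size=n_snv)
    for j, b in enumerate(picks):
        matrix[carrier_rows[b], j] = 1
    return matrix


def drop_infinite_sites_mutations(
    genealogy: GenealogyNode, n_snv: int, positions, seed=None
) -> HapMat:
    """Drop ``n_snv`` infinite-sites mutations on the genealogy.

    Each SNV is placed on a branch drawn uniformly at random; the derived
    allele (1) is carried by exactly the leaves below that branch, so all
    columns are polymorphic and pairwise four-gamete compatible.
    """
    if n_snv < 1:
        raise ValueError("n_snv must be >= 1")
    positions = np.asarray(positions, dtype=float)
    if positions.shape != (n_snv,):
        raise ValueError("one position per SNV required")
    rng = _rng(seed)
    names = genealogy.leaves()
    row_of = {name: i for i, name in enumerate(names)}
    matrix = _mutation_columns(genealogy, n_snv, rng, row_of)
    snv_names = [f"snv{j + 1}" for j in range(n_snv)]
    return create_hapmat(matrix, snv_names, names, positions)


@dataclass
class SimulatedRegion:
    """A simulated genomic region with its generating structure."""

    hapmat: HapMat
    true_trees: list[GenealogyNode]
    breakpoints: tuple[float, ...]
    segment_of_snv: np.ndarray
    seed: int | None = None
    causal_snvs: tuple[int, ...] | None = None
    phenotype: np.ndarray | None = None


def simulate_region_with_recombination(
    n_seq: int,
    n_snv: int,
    breakpoints=(),
    seed=None,
    start: float = 1.0,
    span: float = 2_000_000.0,
    max_tries: int = 100,
) -> SimulatedRegion:
    """Simulate a region with independent genealogies between breakpoints.

    SNV positions are evenly spaced over ``[start, span]`` bp.  Each
    recombination breakpoint (bp) separates two independent genealogies;
    segment boundaries are enforced to be detectable by rejection sampling:
    the segment right of each breakpoint is re-simulated until at least one
    SNV pair spanning the breakpoint fails the four-gamete test (up to
    ``max_tries`` attempts).  With no breakpoints this reduces to a single
    fully compatible genealogy.
    """
    rng = _rng(seed)
    breakpoints = tuple(sorted(float(b) for b in breakpoints))
    if any(b <= start or b >= span for b in breakpoints):
        raise ValueError("breakpoints must lie strictly inside (start, span)")
    # integer bp positions so exported VCFs have valid POS fields
    positions = np.round(np.linspace(start, span, n_snv)).astype(int)
    if n_snv > 1 and not np.all(np.diff(positions) > 0):
        raise ValueError("too many SNVs for the region span")
    seg_of = np.searchsorted(breakpoints, positions, side="left")
    n_seg = len(breakpoints) + 1
    if np.unique(seg_of).size != n_seg:
        raise ValueError("every segment must contain at least one SNV")

    names = [f"h{i + 1}" for i in range(n_seq)]
    row_of = {name: i for i, name in enumerate(names)}
    matrix = np.zeros((n_seq, n_snv), dtype=np.int8)
    trees: list[GenealogyNode] = []
    prev_cols: np.ndarray | None = None
    for s in range(n_seg):
        cols = np.flatnonzero(seg_of == s)
        for attempt in range(max_tries):
            tree = simulate_genealogy(n_seq, rng, names=names)
            block = _mutation_columns(tree, cols.size, rng, row_of)
            if prev_cols is None or _cross_incompatible(prev_cols, block):
                break
        else:
            raise RuntimeError(
                f"no cross-breakpoint incompatibility found after "
                f"{max_tries} attempts before segment {s}"
            )
        matrix[:, cols] = block
        trees.append(tree)
        prev_cols = block
    snv_names = [f"snv{j + 1}" for j in range(n_snv)]
    hapmat = create_hapmat(matrix, snv_names, names, positions)
    return SimulatedRegion(
        hapmat=hapmat,
        true_trees=trees,
        breakpoints=breakpoints,
        segment_of_snv=seg_of,
        seed=seed if isinstance(seed, (int, np.integer)) else None,
    )


def _cross_incompatible(left: np.ndarray, right: np.ndarray) -> bool:
    """True if some column pair across the boundary fails the four-gamete test."""
    for a in left.T:
        for b in right.T:
            if not four_gamete_compatible(a, b):
                return True
    return False


def simulate_phenotype(
    region: SimulatedRegion,
    causal_window: tuple[float, float],
    effect: float,
    seed=None,
    intercept: float | None = None,
) -> tuple[np.ndarray, DistanceMatrix]:
    """Assign a binary phenotype driven by causal SNVs in ``causal_window``.

    Per sequence, the affection probability is
    ``logistic(intercept + effect * c)`` where ``c`` counts the derived
    alleles carried at SNVs inside the causal window (bp, inclusive) and
    ``effect`` is the log-odds per causal allele.  The default intercept
    centers the linear predictor at the sample mean causal-allele count,
    giving roughly balanced phenotypes.  Also returns the 0/1 mismatch
    phenotype distance matrix; both are stored back on ``region``.
    """
    lo, hi = causal_window
    pos = region.hapmat.positions
    causal = np.flatnonzero((pos >= lo) & (pos <= hi))
    if causal.size == 0:
        raise ValueError(
            f"causal window [{lo:g}, {hi:g}] bp contains no SNVs"
        )
    rng = _rng(seed)
    counts = region.hapmat.matrix[:, causal].sum(axis=1).astype(float)
    if intercept is None:
        intercept = -effect * counts.mean()
    eta = intercept + effect * counts
    prob = 1.0 / (1.0 + np.exp(-eta))
    phenotype = (rng.random(region.hapmat.n_seq) < prob).astype(np.int8)
    mismatch = (phenotype[:, None] != phenotype[None, :]).astype(float)
    dist = DistanceMatrix(names=region.hapmat.hap_names, values=mismatch)
    region.causal_snvs = tuple(int(j) for j in causal)
    region.phenotype = phenotype
    return phenotype, dist
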