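"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's own code paths: plain loops,
exhaustive enumeration, and textbook formulas only.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def four_gamete_oracle(a, b) -> bool:
    """Compatible unless the observed 2-bit patterns are all four of 00,01,10,11."""
    patterns = {(int(x), int(y)) for x, y in zip(a, b)}
    return len(patterns) < 4


def rand_index_oracle(labels_a, labels_b) -> float:
    """Enumerate every unordered pair and count agreements."""
    n = len(labels_a)
    agree = total = 0
    for i, j in itertools.combinations(range(n), 2):
        same_a = labels_a[i] == labels_a[j]
        same_b = labels_b[i] == labels_b[j]
        agree += same_a == same_b
        total += 1
    return agree / total


def mantel_oracle(d1, d2) -> float:
    """Pearson r over the strict upper triangles, via scipy."""
    from scipy.stats import pearsonr

    n = d1.shape[0]
    x = [d1[i, j] for i in range(n) for j in range(i + 1, n)]
    y = [d2[i, j] for i in range(n) for j in range(i + 1, n)]
    return float(pearsonr(x, y)[0])


def _gower_oracle(d):
    """-1/2 J D^2 J computed with explicit matrix algebra."""
    n = d.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * J @ (np.asarray(d) ** 2) @ J


def rv_oracle(d1, d2) -> float:
    s1 = _gower_oracle(d1)
    s2 = _gower_oracle(d2)
    return float(
        np.trace(s1 @ s2) / math.sqrt(np.trace(s1 @ s1) * np.trace(s2 @ s2))
    )


def dcor_oracle(d1, d2) -> float:
    """Textbook sample distance correlation from two distance matrices."""
    n = d1.shape[0]

    def center(d):
        a = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                a[i, j] = (
                    d[i, j]
                    - d[i, :].mean()
                    - d[:, j].mean()
                    + d.mean()
                )
        return a

    A = center(np.asarray(d1, dtype=float))
    B = center(np.asarray(d2, dtype=float))
    dcov2 = (A * B).mean()
    dvar1 = (A * A).mean()
    dvar2 = (B * B).mean()
    if dvar1 == 0 or dvar2 == 0:
        return 0.0
    return math.sqrt(max(dcov2, 0.0) / math.sqrt(dvar1 * dvar2))


def hhg_oracle(d1, d2) -> float:
    """Triple loop over (i, j, k); chi-square of each 2x2 table."""
    n = d1.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            a11 = a10 = a01 = a00 = 0
            for k in range(n):
                if k == i or k == j:
                    continue
                x = d1[i, k] <= d1[i, j]
                y = d2[i, k] <= d2[i, j]
                if x and y:
                    a11 += 1
                elif x:
                    a10 += 1
                elif y:
                    a01 += 1
                else:
                    a00 += 1
            den = (a11 + a10) * (a01 + a00) * (a11 + a01) * (a10 + a00)
            if den > 0:
                total += (n - 2) * (a11 * a00 - a10 * a01) ** 2 / den
    return total


def newick_bipartitions(newick: str, sep: str = "-") -> set[frozenset[str]]:
    """Sequence-name sets below every non-root node, read via dendropy.

    Multi-sequence tips (sep-joined labels) are expanded to their names.
    """
    import dendropy

    tree = dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )
    out: set[frozenset[str]] = set()

    def names_below(node) -> frozenset[str]:
        if node.is_leaf():
            label = node.taxon.label if node.taxon else node.label
            return frozenset(label.split(sep))
        return frozenset().union(*(names_below(c) for c in node.child_nodes()))

    for node in tree.seed_node.preorder_iter():
        if node is not tree.seed_node:
            out.add(names_below(node))
    return out


def random_distance_matrix(rng: np.random.Generator, n: int) -> np.ndarray:
    """Euclidean distances of random points: symmetric, zero-diagonal, >= 0."""
    pts = rng.normal(size=(n, 3))
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(d, 0.0)
    return (d + d.T) / 2
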