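"""Association between reconstructed partitions and a comparator.

Per focal SNV, a statistic compares the reconstructed partition with either
a comparator partition (Rand index) or a comparator distance matrix (dCor,
HHG, Mantel, RV applied to the tree's rank-based distances).  Region-wide
significance comes from an omnibus permutation test: the comparator's
sequence labels are permuted, the whole profile is recomputed, and the
observed profile maximum is compared with the permuted maxima using the
add-one p-value (1 + #{max_perm >= max_obs}) / (nperm + 1).

Only the comparator side is ever permuted; the reconstructed trees are fixed,
which preserves the dependence structure of the scan across SNVs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .metrics import ClusterAssignment, DistanceMatrix, cut_k_clusters, rank_distance_matrix
from .tree import PartitionTree, RegionScan

__all__ = [
    "AssociationProfile",
    "rand_index",
    "mantel_stat",
    "rv_coefficient",
    "dcor_stat",
    "hhg_stat",
    "test_dend_asso_ri",
    "test_asso_dist",
    "omnibus_permutation_p",
    "METHODS",
]

METHODS = ("dCor", "HHG", "Mantel", "RV")


@dataclass(frozen=True)
class AssociationProfile:
    """Per-focal-SNV association statistics across a region."""

    snv_names: tuple[str, ...]
    positions: np.ndarray
    statistic: str
    values: np.ndarray
    p_value: float | None = None
    nperm: int = 0
    seed: int | None = None

    def to_csv(self, path: str | Path) -> None:
        """CSV of (snv_name, pos_bp, statistic, value); omnibus p in a comment."""
        with Path(path).open("w") as fh:
            if self.p_value is not None:
                fh.write(
                    f"# omnibus_p={self.p_value:.6g} nperm={self.nperm} "
                    f"seed={self.seed}\n"
                )
            fh.write("snv_name,pos_bp,statistic,value\n")
            for name, pos, val in zip(self.snv_names, self.positions, self.values):
                fh.write(f"{name},{pos:g},{self.statistic},{val:.12g}\n")


# ---------------------------------------------------------------------------
# statistics on aligned arrays
# ---------------------------------------------------------------------------


def _pair_counts(u: np.ndarray, v: np.ndarray) -> float:
    """Rand index from two integer label vectors over the same items."""
    n = u.size
    if n < 2:
        raise ValueError("Rand index requires at least two items")
    _, ui = np.unique(u, return_inverse=True)
    _, vi = np.unique(v, return_inverse=True)
    ku = ui.max() + 1
    kv = vi.max() + 1
    cont = np.bincount(ui * kv + vi, minlength=ku * kv).reshape(ku, kv)
    a = cont.sum(axis=1)
    b = cont.sum(axis=0)

    def c2(x):
        return float(np.sum(x * (x - 1) // 2))

    total = n * (n - 1) // 2
    together_both = c2(cont)
    agree = 2 * together_both + total - c2(a) - c2(b)
    return agree / total


def rand_index(a: ClusterAssignment, b: ClusterAssignment) -> float:
    """Proportion of sequence pairs on which two partitions agree.

    Agreement means the pair is clustered together in both partitions or
    apart in both; the index lies in [0, 1] and equals 1 iff the partitions
    coincide.
    """
    if set(a.names) != set(b.names):
        raise ValueError("partitions cover different sequence names")
    return _pair_counts(np.asarray(a.cluster_ids), b.align(a.names))


def _offdiag(values: np.ndarray) -> np.ndarray:
    n = values.shape[0]
    return values[~np.eye(n, dtype=bool)]


def _mantel_raw(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of off-diagonal entries (== upper-triangle r)."""
    sx = x.std()
    sy = y.std()
    if sx == 0 or sy == 0:
        raise ValueError("Mantel statistic undefined: constant distances")
    return float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))


def mantel_stat(d1: DistanceMatrix, d2: DistanceMatrix) -> float:
    """Mantel statistic: Pearson r of the vectorized strict upper triangles."""
    x = _offdiag(d1.values)
    y = _offdiag(d2.align(d1.names))
    return _mantel_raw(x, y)


def _gower(values: np.ndarray) -> np.ndarray:
    """Double-centered Gower transform -1/2 J D^2 J of a distance matrix."""
    d2 = values**2
    row = d2.mean(axis=1, keepdims=True)
    col = d2.mean(axis=0, keepdims=True)
    return -0.5 * (d2 - row - col + d2.mean())


def _rv_raw(g1: np.ndarray, g2: np.ndarray) -> float:
    num = float(np.sum(g1 * g2))
    den = float(np.sqrt(np.sum(g1 * g1) * np.sum(g2 * g2)))
    if den == 0:
        raise ValueError("RV coefficient undefined: zero configuration")
    return num / den


def rv_coefficient(d1: DistanceMatrix, d2: DistanceMatrix) -> float:
    """RV coefficient of the Gower-centered squared-distance matrices."""
    return _rv_raw(_gower(d1.values), _gower(d2.align(d1.names)))


def _dcenter(values: np.ndarray) -> np.ndarray:
    row = values.mean(axis=1, keepdims=True)
    col = values.mean(axis=0, keepdims=True)
    return values - row - col + values.mean()


def _dcor_raw(a: np.ndarray, b: np.ndarray) -> float:
    dvar1 = float(np.mean(a * a))
    dvar2 = float(np.mean(b * b))
    if dvar1 == 0 or dvar2 == 0:
        return 0.0
    dcov2 = max(float(np.mean(a * b)), 0.0)
    return float(np.sqrt(dcov2 / np.sqrt(dvar1 * dvar2)))


def dcor_stat(d1: DistanceMatrix, d2: DistanceMatrix) -> float:
    """Sample distance correlation between two distance matrices.

    Each matrix is double-centered (row means, column means, grand mean);
    dCov^2 is the mean elementwise product, and dCor is normalized by the
    distance variances.  Degenerate (zero-variance) input gives 0.
    """
    return _dcor_raw(_dcenter(d1.values), _dcenter(d2.align(d1.names)))


def _hhg_raw(d1: np.ndarray, d2: np.ndarray) -> float:
    """HHG statistic: sum of 2x2 chi-squares over ordered pairs (i, j).

    For each ordered pair (i, j), every other point k is classified by
    {d1(i,k) <= d1(i,j)} x {d2(i,k) <= d2(i,j)} (ties inclusive); tables
    with a zero margin contribute 0.
    """
    n = d1.shape[0]
    if n < 3:
        raise ValueError("HHG requires at least 3 points")
    total = 0.0
    for i in range(n):
        x = d1[i]
        y = d2[i]
        # X[j, k] = 1{d1(i,k) <= d1(i,j)}; likewise Y
        X = (x[None, :] <= x[:, None]).astype(np.float64)
        Y = (y[None, :] <= y[:, None]).astype(np.float64)
        valid = np.ones((n, n))
        valid[:, i] = 0.0
        np.fill_diagonal(valid, 0.0)
        Xv = X * valid
        Yv = Y * valid
        a11 = (Xv * Yv).sum(axis=1)
        a10 = (Xv * (valid - Yv)).sum(axis=1)
        a01 = ((valid - Xv) * Yv).sum(axis=1)
        a00 = ((valid - Xv) * (valid - Yv)).sum(axis=1)
        m = n - 2
        r1 = a11 + a10
        r0 = a01 + a00
        c1 = a11 + a01
        c0 = a10 + a00
        den = r1 * r0 * c1 * c0
        num = m * (a11 * a00 - a10 * a01) ** 2
        with np.errstate(divide="ignore", invalid="ignore"):
            chi = np.where(den > 0, num / den, 0.0)
        chi[i] = 0.0  # j == i is not a pair
        total += float(chi.sum())
    return total


def hhg_stat(d1: DistanceMatrix, d2: DistanceMatrix) -> float:
    """Heller-Heller-Gorfine dependence statistic between distance matrices."""
    return _hhg_raw(d1.values, d2.align(d1.names))


def _canonical_method(method: str) -> str:
    for name in METHODS:
        if method.lower() == name.lower():
            return name
    raise ValueError(
        f"unknown method {method!r}; valid options are {', '.join(METHODS)}"
    )


# ---------------------------------------------------------------------------
# omnibus permutation machinery
# ---------------------------------------------------------------------------


def _p_from_maxima(observed_max: float, perm_maxima: np.ndarray) -> float:
    nperm = perm_maxima.size
    return float((1 + np.sum(perm_maxima >= observed_max)) / (nperm + 1))


def omnibus_permutation_p(
    observed_values,
    recompute,
    n_labels: int,
    nperm: int,
    seed: int | None = None,
) -> float:
    """Region-wide permutation p-value for the profile maximum.

    ``recompute(perm)`` must return the profile of statistics obtained after
    re-indexing the comparator's sequence labels by the permutation array
    ``perm``.  The p-value uses the add-one formula, so it lies in
    [1/(nperm+1), 1] and can never be zero.
    """
    if nperm < 1:
        raise ValueError("nperm must be >= 1")
    rng = np.random.default_rng(seed)
    observed_max = float(np.max(observed_values))
    maxima = np.empty(nperm)
    for b in range(nperm):
        maxima[b] = float(np.max(recompute(rng.permutation(n_labels))))
    return _p_from_maxima(observed_max, maxima)


class _ProfileEngine:
    """Vectorized per-method computation of a whole statistic profile.

    Tree-side transforms are precomputed once; evaluating the profile for a
    (possibly permuted) comparator is then a single matrix product for
    Mantel, RV and dCor.  All three transforms commute with joint row/column
    permutation, so permuting the comparator means re-indexing its already
    transformed matrix.  Degenerate tree windows (all sequences identical,
    hence constant distances) contribute statistic 0.
    """

    def __init__(self, method: str, tree_dists: list[np.ndarray], C: np.ndarray):
        self.method = method
        self.C = C
        n = C.shape[0]
        if method == "Mantel":
            T = np.stack([_offdiag(d) for d in tree_dists])
            sd = T.std(axis=1)
            self.degenerate = sd == 0
            sd = np.where(self.degenerate, 1.0, sd)
            self.T = (T - T.mean(axis=1, keepdims=True)) / sd[:, None]
        elif method == "RV":
            G = np.stack([_gower(d).ravel() for d in tree_dists])
            norms = np.sqrt(np.sum(G * G, axis=1))
            self.degenerate = norms == 0
            self.T = G / np.where(self.degenerate, 1.0, norms)[:, None]
        elif method == "dCor":
            A = np.stack([_dcenter(d).ravel() for d in tree_dists])
            self.dvar = np.sum(A * A, axis=1) / (n * n)
            self.degenerate = self.dvar == 0
            self.T = A
        else:  # HHG
            self.T = tree_dists

    def comparator_side(self, perm: np.ndarray | None = None) -> np.ndarray:
        C = self.C if perm is None else self.C[np.ix_(perm, perm)]
        if self.method == "Mantel":
            c = _offdiag(C)
            sd = c.std()
            if sd == 0:
                raise ValueError("Mantel statistic undefined: constant distances")
            return (c - c.mean()) / sd
        if self.method == "RV":
            g = _gower(C).ravel()
            norm = np.sqrt(np.sum(g * g))
            if norm == 0:
                raise ValueError("RV coefficient undefined: zero configuration")
            return g / norm
        if self.method == "dCor":
            return _dcenter(C).ravel()
        return C

    def profile(self, comp) -> np.ndarray:
        if self.method == "Mantel":
            vals = self.T @ comp / comp.size
        elif self.method == "RV":
            vals = self.T @ comp
        elif self.method == "dCor":
            n2 = comp.size
            dvar_c = float(np.sum(comp * comp)) / n2
            if dvar_c == 0:
                return np.zeros(len(self.T))
            dcov2 = np.clip(self.T @ comp / n2, 0.0, None)
            vals = np.sqrt(dcov2 / np.sqrt(self.dvar * dvar_c))
        else:
            return np.array([_hhg_raw(d, comp) for d in self.T])
        return np.where(self.degenerate, 0.0, vals)


def test_asso_dist(
    scan: RegionScan,
    cdmat: DistanceMatrix,
    method: str,
    hapmat=None,
    nperm: int = 0,
    seed: int | None = None,
) -> AssociationProfile:
    """Association profile between a region scan and a comparator distance matrix.

    For each focal SNV the chosen statistic (``dCor``, ``HHG``, ``Mantel`` or
    ``RV``, case-insensitive) compares the tree's rank-based distance matrix
    with ``cdmat``.  With ``nperm > 0`` an omnibus permutation p-value for
    the profile maximum is computed by jointly permuting the rows and columns
    of ``cdmat``.
    """
    meth = _canonical_method(method)
    names = hapmat.hap_names if hapmat is not None else scan.trees[0].hap_names
    C = cdmat.align(names)
    tree_dists = [rank_distance_matrix(t).align(names) for t in scan.trees]
    engine = _ProfileEngine(meth, tree_dists, C)
    observed = engine.profile(engine.comparator_side())

    p_value = None
    if nperm > 0:
        n = len(names)
        rng = np.random.default_rng(seed)
        maxima = np.empty(nperm)
        for b in range(nperm):
            perm = rng.permutation(n)
            maxima[b] = float(engine.profile(engine.comparator_side(perm)).max())
        p_value = _p_from_maxima(float(observed.max()), maxima)

    return AssociationProfile(
        snv_names=scan.snv_names,
        positions=np.asarray(scan.positions),
        statistic=meth,
        values=observed,
        p_value=p_value,
        nperm=nperm,
        seed=seed,
    )


def test_dend_asso_ri(
    scan: RegionScan,
    comparator: PartitionTree | ClusterAssignment,
    k: int,
    nperm: int = 0,
    seed: int | None = None,
) -> AssociationProfile:
    """Rand-index profile between a region scan and a comparator partition.

    A comparator dendrogram is cut into ``k`` clusters; a pre-made
    :class:`ClusterAssignment` is used as-is.  Each reconstructed tree is
    likewise cut into ``k`` clusters (trees with fewer than ``k`` tips fall
    back to their tip partition, with a warning).  With ``nperm > 0`` the
    omnibus p-value permutes the comparator's cluster labels over sequences.
    """
    if isinstance(comparator, PartitionTree):
        comp = cut_k_clusters(comparator, k)
    else:
        comp = comparator
    names = scan.trees[0].hap_names
    comp_labels = comp.align(names)
    tree_labels = []
    for t in scan.trees:
        if t.n_tips < k:
            warnings.warn(
                f"tree at focal SNV {t.focal_name!r} has {t.n_tips} tips < "
                f"k={k}; using its tip partition",
                stacklevel=2,
            )
            tree_labels.append(cut_k_clusters(t, t.n_tips).cluster_ids)
        else:
            tree_labels.append(cut_k_clusters(t, k).cluster_ids)
    observed = np.array(
        [_pair_counts(tl, comp_labels) for tl in tree_labels]
    )
    p_value = None
    if nperm > 0:
        p_value = omnibus_permutation_p(
            observed,
            lambda perm: [
                _pair_counts(tl, comp_labels[perm]) for tl in tree_labels
            ],
            n_labels=len(names),
            nperm=nperm,
            seed=seed,
        )
    return AssociationProfile(
        snv_names=scan.snv_names,
        positions=np.asarray(scan.positions),
        statistic="RI",
        values=observed,
        p_value=p_value,
        nperm=nperm,
        seed=seed,
    )
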