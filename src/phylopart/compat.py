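"""SNV compatibility and neighborhood selection around a focal SNV.

Two diallelic sites are *compatible* with a single-mutation history (infinite
sites, no recombination) unless all four gamete patterns 00, 01, 10, 11 occur
among the sequences — the Four-Gamete Test.  The neighborhood of a focal SNV
is grown outward on each side while sites remain compatible with the focal
site, then padded with the physically nearest remaining sites up to a minimum
window size.  Compatible sites are ordered from most ancient to most recent
using minor allele frequency (MAF) as an age proxy; incompatible (padding)
sites are ordered by physical proximity to the focal site.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .hapmat import HapMat

__all__ = [
    "Neighborhood",
    "four_gamete_compatible",
    "default_min_window",
    "minor_allele_frequency",
    "select_neighborhood",
    "order_neighborhood",
]


def four_gamete_compatible(col_a, col_b) -> bool:
    """Four-Gamete Test: False iff all of 00, 01, 10, 11 occur.

    ``col_a`` and ``col_b`` are equal-length 0/1 vectors giving the alleles
    of two SNVs across the same sequences.
    """
    a = np.asarray(col_a)
    b = np.asarray(col_b)
    if a.shape != b.shape:
        raise ValueError(f"column lengths differ: {a.shape} vs {b.shape}")
    # 2-bit pattern per sequence; incompatible iff all four patterns occur
    patterns = a * 2 + b
    return np.unique(patterns).size < 4


def minor_allele_frequency(col) -> float:
    """MAF = min(p, 1-p) where p is the frequency of the derived allele 1."""
    p = float(np.mean(col))
    return min(p, 1.0 - p)


def default_min_window(total_snvs: int) -> int:
    """Default minimum window: max(1, ceiling of 2% of the SNV count)."""
    if total_snvs < 1:
        raise ValueError(f"total_snvs must be positive, got {total_snvs}")
    return max(1, math.ceil(0.02 * total_snvs))


@dataclass(frozen=True)
class Neighborhood:
    """Contiguous SNV window around a focal SNV.

    ``compatible_indices`` holds the focal SNV and the sites added during
    compatible expansion, ordered most ancient to most recent (decreasing
    MAF).  ``incompatible_indices`` holds the padding sites, ordered by
    physical proximity to the focal SNV.  Together they cover the contiguous
    index range ``lower_index..upper_index``.
    """

    focal_index: int
    lower_index: int
    upper_index: int
    lower_pos: float
    upper_pos: float
    compatible_indices: tuple[int, ...]
    incompatible_indices: tuple[int, ...]
    compatible_names: tuple[str, ...] = ()
    incompatible_names: tuple[str, ...] = ()

    @property
    def size(self) -> int:
        return self.upper_index - self.lower_index + 1

    @property
    def indices(self) -> tuple[int, ...]:
        """All window columns in physical (index) order."""
        return tuple(range(self.lower_index, self.upper_index + 1))


def select_neighborhood(
    hapmat: HapMat, focal_index: int, min_window: int | None = None
) -> Neighborhood:
    """Grow the compatibility window around ``focal_index`` and classify it.

    Expansion proceeds independently to the left and right, admitting each
    adjacent SNV while it passes the Four-Gamete Test against the focal SNV
    and stopping (exclusive) at the first incompatible SNV.  If fewer than
    ``min_window`` SNVs result, the window is padded with the not-yet-included
    adjacent SNV whose bp distance to the focal SNV is smallest (ties go
    left), until the minimum size is reached or the region is exhausted.
    Padding SNVs are classified as incompatible regardless of their own
    four-gamete status with the focal SNV, because they lie beyond the first
    incompatibility boundary.
    """
    n_snv = hapmat.n_snv
    if not 0 <= focal_index < n_snv:
        raise IndexError(f"focal index {focal_index} out of range 0..{n_snv - 1}")
    if min_window is None:
        min_window = default_min_window(n_snv)
    if min_window < 1:
        raise ValueError(f"min_window must be >= 1, got {min_window}")

    focal_col = hapmat.column(focal_index)
    lower = focal_index
    while lower > 0 and four_gamete_compatible(focal_col, hapmat.column(lower - 1)):
        lower -= 1
    upper = focal_index
    while upper < n_snv - 1 and four_gamete_compatible(
        focal_col, hapmat.column(upper + 1)
    ):
        upper += 1

    compatible = list(range(lower, upper + 1))
    incompatible: list[int] = []
    target = min(min_window, n_snv)
    pos = hapmat.positions
    focal_pos = pos[focal_index]
    while (upper - lower + 1) < target:
        left = lower - 1 if lower > 0 else None
        right = upper + 1 if upper < n_snv - 1 else None
        if left is not None and right is not None:
            # tie in bp distance goes to the left (smaller position)
            if abs(pos[left] - focal_pos) <= abs(pos[right] - focal_pos):
                pick = left
            else:
                pick = right
        else:
            pick = left if left is not None else right
        if pick == lower - 1:
            lower = pick
        else:
            upper = pick
        incompatible.append(pick)

    compatible_ordered = _order_compatible(hapmat, compatible, focal_index)
    incompatible_ordered = _order_incompatible(hapmat, incompatible, focal_index)
    return Neighborhood(
        focal_index=focal_index,
        lower_index=lower,
        upper_index=upper,
        lower_pos=float(pos[lower]),
        upper_pos=float(pos[upper]),
        compatible_indices=tuple(compatible_ordered),
        incompatible_indices=tuple(incompatible_ordered),
        compatible_names=tuple(hapmat.snv_names[j] for j in compatible_ordered),
        incompatible_names=tuple(hapmat.snv_names[j] for j in incompatible_ordered),
    )


def _order_compatible(hapmat: HapMat, cols: list[int], focal_index: int) -> list[int]:
    """Most ancient (largest MAF) first; ties by proximity, then column index."""
    pos = hapmat.positions
    focal_pos = pos[focal_index]
    return sorted(
        cols,
        key=lambda j: (
            -minor_allele_frequency(hapmat.column(j)),
            abs(pos[j] - focal_pos),
            j,
        ),
    )


def _order_incompatible(hapmat: HapMat, cols: list[int], focal_index: int) -> list[int]:
    """Closest to the focal SNV first; ties by smaller position."""
    pos = hapmat.positions
    focal_pos = pos[focal_index]
    return sorted(cols, key=lambda j: (abs(pos[j] - focal_pos), pos[j]))


def order_neighborhood(hapmat: HapMat, nbhd: Neighborhood) -> list[int]:
    """Partitioning order: MAF-ordered compatible SNVs, then padding by proximity."""
    return list(nbhd.compatible_indices) + list(nbhd.incompatible_indices)
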