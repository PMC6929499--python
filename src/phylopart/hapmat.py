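"""Binary haplotype matrix container and I/O.

A :class:`HapMat` holds phased, diallelic SNV data: a 0/1 matrix whose rows
are haplotype sequences and whose columns are SNVs, together with sequence
names, SNV names, and physical positions in base pairs.  Allele 1 is the
derived (ALT) allele; allele 0 is ancestral (REF).  Positions must be
strictly increasing, so columns are always in physical order along one
chromosome.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "HapMat",
    "HapMatError",
    "create_hapmat",
    "hapmat_from_table",
    "hapmat_from_vcf",
    "write_table",
    "write_vcf",
]


class HapMatError(ValueError):
    """Raised when haplotype data violate the HapMat contract."""


@dataclass(frozen=True)
class HapMat:
    """Sequences-by-SNVs binary matrix with names and bp positions.

    Parameters
    ----------
    matrix : ndarray of shape (n_seq, n_snv)
        Entries are 0 (ancestral allele) or 1 (derived allele).
    hap_names : tuple of str
        Unique row labels, one per sequence.
    snv_names : tuple of str
        Unique column labels, one per SNV.
    positions : ndarray of shape (n_snv,)
        Strictly increasing physical positions in base pairs.
    """

    matrix: np.ndarray
    hap_names: tuple[str, ...]
    snv_names: tuple[str, ...]
    positions: np.ndarray

    def __post_init__(self) -> None:
        mat = np.asarray(self.matrix)
        if mat.ndim != 2:
            raise HapMatError(f"matrix must be 2-D, got {mat.ndim}-D")
        hap_names = tuple(str(h) for h in self.hap_names)
        snv_names = tuple(str(s) for s in self.snv_names)
        pos = np.asarray(self.positions, dtype=float)
        if len(hap_names) != mat.shape[0]:
            raise HapMatError(
                f"{len(hap_names)} sequence names for {mat.shape[0]} rows"
            )
        if len(snv_names) != mat.shape[1] or pos.shape != (mat.shape[1],):
            raise HapMatError(
                f"{len(snv_names)} SNV names / {pos.size} positions "
                f"for {mat.shape[1]} columns"
            )
        bad = (mat != 0) & (mat != 1)
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise HapMatError(
                f"non-binary entry {mat[i, j]!r} at sequence "
                f"{hap_names[i]!r} (row {i}), SNV {snv_names[j]!r} (column {j})"
            )
        if len(set(hap_names)) != len(hap_names):
            raise HapMatError("sequence names are not pairwise distinct")
        if len(set(snv_names)) != len(snv_names):
            raise HapMatError("SNV names are not pairwise distinct")
        if pos.size and not np.all(np.diff(pos) > 0):
            k = int(np.flatnonzero(np.diff(pos) <= 0)[0])
            raise HapMatError(
                "positions must be strictly increasing; "
                f"position {pos[k + 1]:g} of {snv_names[k + 1]!r} does not "
                f"exceed {pos[k]:g} of {snv_names[k]!r}"
            )
        object.__setattr__(self, "matrix", np.ascontiguousarray(mat, dtype=np.int8))
        object.__setattr__(self, "hap_names", hap_names)
        object.__setattr__(self, "snv_names", snv_names)
        object.__setattr__(self, "positions", pos)
        self.positions.setflags(write=False)
        self.matrix.setflags(write=False)

    @property
    def n_seq(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_snv(self) -> int:
        return self.matrix.shape[1]

    def column(self, j: int) -> np.ndarray:
        """Return SNV column ``j`` as a read-only 0/1 vector."""
        return self.matrix[:, j]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HapMat):
            return NotImplemented
        return (
            self.hap_names == other.hap_names
            and self.snv_names == other.snv_names
            and np.array_equal(self.positions, other.positions)
            and np.array_equal(self.matrix, other.matrix)
        )


def create_hapmat(matrix, snv_names, hap_names, positions) -> HapMat:
    """Validate raw pieces and assemble a :class:`HapMat`.

    Argument order mirrors the field names users supply: the 0/1 matrix,
    SNV (column) names, sequence (row) names, and bp positions.
    """
    return HapMat(
        matrix=np.asarray(matrix),
        hap_names=tuple(hap_names),
        snv_names=tuple(snv_names),
        positions=np.asarray(positions),
    )


# ---------------------------------------------------------------------------
# Delimited-text format: one header row of SNV names, one row of positions,
# then one row per sequence.  The first cell of each row is a label.
# ---------------------------------------------------------------------------

_POS_LABEL = "pos"


def hapmat_from_table(path: str | Path, delimiter: str = ",") -> HapMat:
    """Read a HapMat from the delimited text format written by :func:`write_table`."""
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        rows = [row for row in reader if row]
    if not rows:
        raise HapMatError(f"{path}: empty file")
    header = rows[0]
    if len(rows) < 3:
        raise HapMatError(f"{path}: expected header, position row and data rows")
    width = len(header)
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise HapMatError(
                f"{path}: line {lineno} has {len(row)} fields, expected {width}"
            )
    snv_names = header[1:]
    pos_row = rows[1]
    if pos_row[0] != _POS_LABEL:
        raise HapMatError(
            f"{path}: line 2 must be the position row labelled {_POS_LABEL!r}"
        )
    try:
        positions = [float(x) for x in pos_row[1:]]
    except ValueError as exc:
        raise HapMatError(f"{path}: non-numeric position: {exc}") from None
    hap_names = [row[0] for row in rows[2:]]
    try:
        matrix = np.array([[int(x) for x in row[1:]] for row in rows[2:]])
    except ValueError as exc:
        raise HapMatError(f"{path}: non-integer genotype: {exc}") from None
    return create_hapmat(matrix, snv_names, hap_names, positions)


def write_table(hapmat: HapMat, path: str | Path, delimiter: str = ",") -> None:
    """Write a HapMat in the delimited text format (round-trips bit-exactly)."""
    path = Path(path)
    pos = hapmat.positions
    pos_cells = [
        str(int(p)) if float(p).is_integer() else repr(float(p)) for p in pos
    ]
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(["hap", *hapmat.snv_names])
        writer.writerow([_POS_LABEL, *pos_cells])
        for i, name in enumerate(hapmat.hap_names):
            writer.writerow([name, *map(str, hapmat.matrix[i].tolist())])


# ---------------------------------------------------------------------------
# VCF input/output (phased, diallelic, GT-only)
# ---------------------------------------------------------------------------


def hapmat_from_vcf(path: str | Path) -> HapMat:
    """Build a HapMat from a VCF of phased, diallelic, complete genotypes.

    Each diploid sample contributes two rows named ``<sample>_1`` and
    ``<sample>_2``; allele 1 in the matrix is the ALT allele.  SNV names come
    from the ID column, or ``<chrom>:<pos>`` when ID is missing.  All records
    must lie on a single chromosome (a reconstruction window cannot span
    chromosomes) and genotypes must be phased with no missing alleles.
    """
    from cyvcf2 import VCF

    path = Path(path)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise HapMatError(f"{path}: VCF contains no samples")
    chroms: set[str] = set()
    records: list[tuple[float, str, np.ndarray]] = []
    for variant in vcf:
        where = f"{variant.CHROM}:{variant.POS}"
        if len(variant.ALT) != 1:
            raise HapMatError(
                f"{path}: record {where} has ALT {variant.ALT!r}; "
                "exactly one alternative allele is required"
            )
        chroms.add(variant.CHROM)
        if len(chroms) > 1:
            raise HapMatError(
                f"{path}: multiple chromosomes ({sorted(chroms)}); "
                "supply one chromosome per file"
            )
        alleles = np.empty(2 * len(samples), dtype=np.int8)
        for k, gt in enumerate(variant.genotypes):
            a, b, phased = gt[0], gt[1], gt[2]
            if a < 0 or b < 0:
                raise HapMatError(
                    f"{path}: missing genotype for sample "
                    f"{samples[k]!r} at {where}"
                )
            if not phased:
                raise HapMatError(
                    f"{path}: unphased genotype for sample {samples[k]!r} "
                    f"at {where}; the method requires phased data"
                )
            alleles[2 * k] = a
            alleles[2 * k + 1] = b
        name = variant.ID if variant.ID not in (None, ".") else where
        records.append((float(variant.POS), name, alleles))
    vcf.close()
    if not records:
        raise HapMatError(f"{path}: VCF contains no records")
    records.sort(key=lambda r: r[0])
    positions = [r[0] for r in records]
    snv_names = [r[1] for r in records]
    matrix = np.column_stack([r[2] for r in records])
    hap_names = [f"{s}_{i}" for s in samples for i in (1, 2)]
    return create_hapmat(matrix, snv_names, hap_names, positions)


def write_vcf(hapmat: HapMat, path: str | Path, chrom: str = "1") -> None:
    """Write a HapMat as a phased, diallelic VCF (text, GT field only).

    Consecutive row pairs form pseudo-diploid samples.  When row names
    follow the ``<sample>_1`` / ``<sample>_2`` convention the sample name is
    recovered; otherwise samples are named ``ind1``, ``ind2``, ...  REF/ALT
    alleles are synthetic placeholders (A/T): only the 0/1 coding matters.
    """
    if hapmat.n_seq % 2:
        raise HapMatError("VCF export requires an even number of sequences")
    path = Path(path)
    names = hapmat.hap_names
    samples = []
    for k in range(hapmat.n_seq // 2):
        a, b = names[2 * k], names[2 * k + 1]
        if a.endswith("_1") and b == a[:-2] + "_2":
            samples.append(a[:-2])
        else:
            samples.append(f"ind{k + 1}")
    with Path(path).open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for j in range(hapmat.n_snv):
            pos = hapmat.positions[j]
            if not float(pos).is_integer():
                raise HapMatError(
                    f"VCF POS must be an integer; SNV "
                    f"{hapmat.snv_names[j]!r} is at {pos!r} bp"
                )
            pos_str = str(int(pos))
            gts = "\t".join(
                f"{hapmat.matrix[2 * k, j]}|{hapmat.matrix[2 * k + 1, j]}"
                for k in range(hapmat.n_seq // 2)
            )
            fh.write(
                f"{chrom}\t{pos_str}\t{hapmat.snv_names[j]}\tA\tT\t.\t.\t.\tGT\t{gts}\n"
            )
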