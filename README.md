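# phylopart

Local perfect-phylogeny partitions of binary haplotypes, and
distance-matrix association scans across a genomic region.

## What problem this solves

A perfect phylogeny is a rooted binary tree that recursively partitions a
sample of DNA sequences: under the infinite-sites model every diallelic SNV
mutates once, so the carriers of its derived allele form a clade.  The
nested partitions near a trait-influencing variant carry information about
ancestry — case haplotypes tend to cluster — which makes locally
reconstructed partitions useful for fine-mapping.  Recombination breaks
compatibility along the chromosome, so `phylopart` reconstructs the
partition *locally*: around each focal SNV it grows a window of sites that
pass the Four-Gamete Test against the focal site (incompatible iff all four
gamete patterns 00, 01, 10, 11 occur), orders the window's compatible sites
from oldest to youngest by minor allele frequency, and recursively splits
the sample by derived-allele carrier status.  Sequences identical across
the window share a tip (`h1-h3`).

Scanning every focal SNV yields a sequence of trees that can be tested,
region-wide, against a comparator partition (Rand index) or a comparator
distance matrix — e.g. phenotype mismatch distances — with dCor, HHG,
Mantel, or RV statistics computed on the trees' rank-based distances
(pair separated at split depth r of L levels ↦ distance (L − r + 1)/L).
Significance comes from an omnibus permutation test of the profile maximum:
comparator labels are permuted, the profile is recomputed, and
p = (1 + #{perm max ≥ observed max})/(nperm + 1).

It is intended for population-level phased, diallelic data; phasing,
imputation and multi-allelic markers are out of scope.

## Worked example

```python
import phylopart as pp

# 30 haplotypes, 60 SNVs over 210 kbp, recombination at 70 and 140 kbp;
# a binary phenotype driven by derived alleles in the middle segment
region = pp.simulate_region_with_recombination(
    n_seq=30, n_snv=60, breakpoints=[70_000, 140_000], seed=11, span=210_000)
y, pdist = pp.simulate_phenotype(region, (70_001, 140_000), effect=2.0, seed=12)

# one local tree, at the 31st SNV
tree = pp.reconstruct_pp(region.hapmat, focal_snv=30)
print(tree.lower_pos, tree.upper_pos, tree.n_tips)   # 1.0 210000.0 30
print(pp.to_newick(tree))                            # ((((h13,(((h16,h17),h11),...

# the region scan and the dCor association profile vs phenotype distances
scan = pp.reconstruct_pp_region(region.hapmat)       # 60 trees
prof = pp.test_asso_dist(scan, pdist, "dCor", hapmat=region.hapmat,
                         nperm=999, seed=1)
print(prof.values.max(), prof.positions[prof.values.argmax()])
# 0.5107...  110339.0   <- profile peaks inside the causal segment
print(prof.p_value)
# 0.026                 <- omnibus permutation p-value
```

The peak of the dCor profile (0.511 at 110,339 bp) falls inside the causal
segment (70–140 kbp), and the omnibus test rejects region-wide independence
(p = 0.026 with 999 permutations).

The same workflow is available from the shell:

```sh
phylopart simulate --n-seq 30 --n-snv 60 --span 210000 \
    --breakpoints 70000,140000 --causal-lower 70001 --causal-upper 140000 \
    --effect 2 --seed 11 --out-dir sim --vcf
phylopart reconstruct --input sim/hapmat.csv --out-dir trees
phylopart associate --input sim/hapmat.csv --method dCor \
    --cdmat sim/phenotype_dist.csv --nperm 999 --seed 1 --out-dir asso
```

Inputs may be the package's delimited format (header of SNV names, a
position row, one row per sequence) or a VCF restricted to phased,
diallelic, complete genotypes on one chromosome.  See `docs/methods.md` for
the model, parameter meanings, and design decisions.

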