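# Methods

## The model

A perfect phylogeny over a sample of phased binary sequences is a rooted
binary tree that recursively partitions the sequences: under the
infinite-sites model each diallelic SNV mutates once, so the carriers of a
derived allele form a clade, and a set of mutually compatible SNVs defines a
nested partition.  `phylopart` reconstructs such a partition *locally*,
around a focal SNV, because recombination breaks compatibility along a
chromosome: demanding a genome-wide perfect phylogeny would either fail or
collapse to a useless coarse partition.

Reconstruction at a focal SNV has three steps:

1. **Window.**  Starting at the focal SNV, the window grows outward in each
   direction, admitting each adjacent SNV while it passes the Four-Gamete
   Test against the focal SNV (two sites are incompatible iff all four
   gamete patterns 00, 01, 10, 11 occur).  Growth stops, per side, at the
   first incompatible site (exclusive).  If the window is smaller than a
   minimum size — by default `max(1, ceil(0.02 * n_snv))`, e.g. 55 for a
   2747-SNV panel — it is padded with the physically nearest remaining
   sites, which are classified as incompatible regardless of their own
   four-gamete status because they lie beyond the first incompatibility
   boundary.
2. **Order.**  Compatible window SNVs are sorted from most ancient to most
   recent using minor allele frequency (MAF = min(p, 1−p)) as an age proxy,
   largest MAF first: under infinite sites, older variants have had more
   time to drift upward in frequency.  Ties break by physical proximity to
   the focal SNV, then by column index.  Incompatible (padding) SNVs follow,
   ordered by proximity to the focal SNV, ties to the smaller position.
3. **Partition.**  One cluster holds all sequences; the ordered SNVs are
   processed once, left to right, and each SNV splits every active cluster
   that is polymorphic at it into its allele-0 and allele-1 (derived
   carrier) subclusters.  A SNV monomorphic within a cluster is skipped for
   that cluster, so every internal node is strictly binary.  Sequences
   identical over every window SNV can never be separated and end in one
   tip whose label joins their names with a separator (default `-`).

The coded allele 1 is treated as derived (ALT in VCF input); no frequency
recoding is applied.  Trees carry no branch lengths — the method defines
none — so Newick output is topology-only, and a single-tip tree is written
as a bare leaf (`a-b;`).

## Association testing

A region scan reconstructs one tree per focal SNV.  Each tree is compared
with a user comparator:

- **Rand index** against a comparator partition, or a comparator dendrogram
  cut into `k` clusters.  Cutting replays the tree's splits in creation
  order (the order the recursive partitioning performed them), the analogue
  of lowering a dendrogram cut height.  A tree with fewer than `k` tips
  falls back to its tip partition with a warning.
- **dCor, HHG, Mantel, RV** against a comparator distance matrix, using the
  tree's *rank-based distances*: with `L` split levels on the deepest
  root-to-tip path, a pair first separated at depth `r` (root split = 1)
  gets distance `(L − r + 1)/L`; same-tip pairs get 0.  The exact numeric
  scale is a package choice: any strictly monotone reparameterization gives
  the same permutation null, and the same transform is used on both sides
  of every self-comparison, so the anchor points (0 for indistinguishable,
  1 for root-separated) are what matter.

Statistic definitions: Mantel is the Pearson correlation of the strict
upper triangles; RV is `tr(S1 S2)/sqrt(tr(S1²) tr(S2²))` with `S = −½ J D² J`
the Gower transform; dCor double-centers each distance matrix and uses
`dCov² = mean(A∘B)` with the zero-variance convention dCor = 0; HHG sums,
over ordered pairs `(i, j)`, the Pearson chi-square of the 2×2 table
classifying every other point `k` by `{d1(i,k) ≤ d1(i,j)} × {d2(i,k) ≤
d2(i,j)}` (ties inclusive; zero-margin tables contribute 0).

**Omnibus test.**  Region-wide significance uses the maximum of the profile
as the scan statistic.  The comparator's sequence labels are permuted
(jointly re-indexing the rows and columns of the comparator matrix, or
shuffling the comparator partition over sequences); the reconstructed trees
are never recomputed, which preserves the dependence of the scan across
SNVs.  The p-value uses the add-one formula
`p = (1 + #{perm max ≥ observed max})/(nperm + 1)`, so `p ∈ [1/(nperm+1), 1]`
and is reproducible from the seed.  Under an exchangeable null the test is
exact: rejection at level α occurs with probability α (up to the
granularity of `nperm`).  Degenerate windows in which all sequences are
identical produce constant rank distances; their statistic is defined as 0
(no association information) rather than an error, so one collapsed window
cannot abort a whole scan.

## Synthetic data

The generator emulates the structure of phased population-level resequencing
data used to exercise the method:

- **Genealogy**: a random rooted binary topology by iterative uniform
  pairwise joins (Yule-type).  No waiting times are drawn because the
  reconstruction uses topology only; this is a deliberate simplification of
  the coalescent.
- **Mutations**: each SNV is placed on a branch drawn uniformly at random;
  derived carriers are exactly the leaves below it.  All columns are
  polymorphic, and within a non-recombining segment every pair of columns
  passes the four-gamete test.  Uniform branch choice (rather than
  length-proportional) is a simplification consistent with the topology-only
  genealogy.
- **Recombination**: breakpoints split the region into segments with
  independent genealogies.  Rejection sampling guarantees at least one
  incompatible SNV pair across every breakpoint (up to 100 attempts), so
  windowing always has a signal to detect.  SNV positions are evenly spaced
  integers across the span (default 2 Mbp).
- **Phenotype**: binary, from a logistic model
  `P(affected) = logistic(intercept + effect × causal-allele count)` with
  the causal SNVs taken from a bp window.  The default intercept centers
  the linear predictor at the sample-mean causal count, giving roughly
  balanced phenotypes.  The phenotype distance matrix is the 0/1 mismatch
  indicator.

What this does **not** emulate: coalescent branch lengths and the resulting
frequency spectrum, mutation/recombination-rate heterogeneity, gene
conversion, selection, genotyping error, and case-control ascertainment.
Tests passing on these simulations therefore validate the algorithmic
contracts and the statistical calibration of the permutation test, not
robustness to the full complexity of real resequencing data.

## Problem sizes and checks

The automated checks run at desk scale, chosen to keep the full suite in a
few minutes while leaving Monte-Carlo error small relative to the margins
asserted:

- Four-gamete test: exhaustive agreement with pattern enumeration over all
  2⁶ × 2⁶ pairs of 6-sequence columns.
- Recovery: 200 compatible datasets of 12 sequences × 30 SNVs.  Every split
  performed uses an SNV whose carrier set is a clade of the generating
  genealogy, the derived-side child equals cluster ∩ clade, and tips are
  exactly the identical-haplotype classes.  The stronger claim — that every
  *cluster* of the output is itself a clade or complement slice of the true
  tree — holds only when every genealogy branch carries at least one
  mutation, and is asserted separately under that condition; with 30
  mutations over 22 branches, uncovered branches are common, and a cluster
  formed as "clade minus a non-child subclade" is then not a true-tree
  edge.  This is a property of recursive partitioning under incomplete
  characters, not an implementation artifact.
- Statistics: dCor, RV, Mantel, HHG match independent brute-force oracles
  to 12 decimals (Rand index exactly) on 100 random 5–8 point instances.
- Calibration: 500 null replicates (20 × 40, independent comparator,
  nperm = 199); rejection at α = 0.05 must fall in the binomial 99%
  interval [0.025, 0.075] for Mantel and dCor.
- Localization: 100 replicates of 30 × 100 with five recombination segments
  and a strong causal effect (2.0 log-odds per allele) in the middle
  segment; the dCor profile must peak inside the causal subregion in a
  majority (observed ≈ 80%).

## Numerical and design choices

- Strictly increasing positions are required; duplicate positions are
  rejected at load rather than silently tie-broken, because physical
  proximity ordering is ill-defined under duplicates.
- Monomorphic columns are accepted (they never split anything).
- Windows are tested pairwise against the focal SNV only; mutual
  incompatibility among non-focal window SNVs is tolerated and resolved by
  the partition order.
- Split children are ordered allele-0 first; this affects Newick text but
  not topology.
- VCF input requires phased, diallelic records with complete genotypes on a
  single chromosome; haplotypes are named `<sample>_1` / `<sample>_2` and
  ALT is coded 1, a deterministic reversible mapping.
- Comparator dendrograms read from plain Newick carry no split ranks; ranks
  are assigned breadth-first from the root (depth, then left-to-right), the
  closest analogue of cutting at successively lower heights.
- The omnibus summary is the profile maximum — the standard scan statistic;
  the mean would dilute a localized signal across a long region.
- `scripts/acceptance.py` re-derives every reported number at run time from
  the seed passed on the command line; nothing is hard-coded except the
  problem sizes above.

## Known limitations

- The method requires phased, complete, diallelic data; no imputation,
  phasing, or multi-allelic support.
- Rank distances ignore branch lengths (none exist), so comparators built
  from time-calibrated trees are compared only through their nested
  partition structure.
- Per-SNV pointwise p-values are deliberately not provided; the permutation
  test is region-wide (omnibus) only.
- Region scans rebuild each window from scratch; cost grows linearly in
  SNVs and roughly quadratically in sequences, which is fine at the sizes
  above but slow for biobank-scale panels.
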