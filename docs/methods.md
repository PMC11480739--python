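# Methods

This note documents the statistical procedures, defaults and numerical
choices behind snpdesk, and what its synthetic data do and do not emulate.

## Genotype coding and VCF handling

Genotypes are unphased throughout: `0/1`, `1/0` and `0|1` all code as the
heterozygous state 1. Half-calls (`./0`) code as missing (−1), which keeps
call-rate semantics conservative. Ploidy is fixed at two; a haploid call is
doubled. Multiallelic alternates collapse to one "alternate" state at
encoding time only — the viewer-style heatmap distinguishes just four
states — while the site index and all comparison logic retain the full
allele lists, since concordance classification depends on allele identity.

SNP extraction keeps alleles that are single-base substitutions (REF and
ALT both length 1). At sites mixing SNP and indel alternates the indel
alternates are dropped and genotype allele indices renumbered; a genotype
carrying a dropped allele becomes missing, consistent with the half-call
rule. Sites left with no alternates are dropped. No left-alignment or
atomization of complex alleles is attempted; inputs are assumed normalized
upstream, and filtering is by allele type only.

Coordinates are 1-based inclusive everywhere, matching VCF.

## Per-site statistics

For each site, over the n called (non-missing) genotypes with het count
n_Aa and hom-alt count n_aa:

- call_rate = n / N, f_missing = 1 − call_rate;
- alternate allele frequency p = (n_Aa + 2 n_aa) / 2n, maf = min(p, 1−p);
- frac_het = n_Aa / n.

The Hardy–Weinberg test is the exact conditional (Levene–Haldane) test: the
distribution of the heterozygote count given the conditioned allele counts,

P(n_Aa | n_A, n_a) = n! / (n_AA! n_Aa! n_aa!) · 2^{n_Aa} · n_A! n_a! / (2n)!,

computed with log-gamma arithmetic and renormalized. The two-sided p-value
(`HWE`) sums all heterozygote counts whose probability does not exceed the
observed one (with a 1e−12 relative tolerance guarding float ties); the
excess-heterozygosity p-value (`ExcHet`) is the upper tail
P(n_Aa ≥ observed). No mid-p correction is applied. Monomorphic or
all-missing sites report (1, 1). The test suite verifies both values
against a brute-force rational-arithmetic enumeration for every genotype
configuration with n ≤ 50.

Filter expressions use bcftools-style precedence (comparisons bind tighter
than `&`/`|`), the tags F_MISSING, MAF, AF, QUAL, ExcHet, HWE, CALL_RATE,
FRAC_HET and DP/MEAN_DP, and the operators `<, <=, >, >=, ==`. A comparison
on a tag absent for a site (e.g. QUAL on a store without QUAL) is false for
that site. Unknown tags are rejected at parse time.

−log10 transforms for plotting clip p-values at 1e−30 so plotted values are
finite.

## LD pruning

Composite (genotype-level) LD: r² is the squared Pearson correlation of
0/1/2 codes over pairwise-complete samples — not haplotype-EM r², which
would require phase. The scan is greedy left-to-right within each
chromosome: a site is removed when r² with any already-retained site within
`window_bp` (default 100 kb) upstream exceeds `r2_max` (default 0.8), so
the leftmost site of a correlated pair is always kept. Zero-variance sites
are retained and never trigger removals. The output provably contains no
retained within-window pair above the threshold, which the suite asserts
directly.

## Distances, clustering and trees

For samples x, y over the m sites where both are called:

- hamming_fraction = (# sites with differing codes) / m;
- one_minus_ibs = 1 − (shared alleles) / 2m, with 2 − |code_x − code_y|
  shared alleles per site.

hamming_fraction ≥ one_minus_ibs always (a mismatching genotype still
shares at most one of two alleles). Pairs with m = 0 get distance 1 and a
warning rather than an error, since downstream tree building needs a
complete matrix.

Hierarchical clustering uses scipy linkage (average by default for the
haplotype viewer; complete linkage to emulate plink-style clustering, used
by the loci ranking). Leaf order is deterministic: at each internal node
the subtree containing the smaller minimum original sample index comes
first. K-cluster cuts replay the merge sequence and stop n − k merges in,
so exactly k clusters always result regardless of tied heights; cluster
ids are assigned by each cluster's smallest sample index.

Neighbor joining is the standard Saitou–Nei algorithm; Q-matrix ties break
toward the smallest (i, j) index pair, and a negative branch length is
clamped to zero with the deficit moved to its sibling so the pair's summed
length is preserved. The result is an unrooted tree serialized as Newick
with branch lengths. Maximum-likelihood tree building is out of scope; the
distance-based path is the one implemented.

Classical (Torgerson) MDS double-centers −½ J D² J, eigendecomposes, and
keeps the top `n_components` (default 5) non-negative eigenvalues;
coordinates are eigenvectors scaled by √λ. Negative eigenvalues (non-
Euclidean input) are truncated to zero with a warning. Each coordinate
column is sign-fixed so its largest-magnitude entry is positive, making
output deterministic. Note this operates on the package's own 1−IBS
distances; portals that compute MDS from an identity-by-descent matrix
estimated by external tools will differ — IBD estimation is not
implemented here.

The heatmap layout fixes the viewer color coding: 0 gray, 1 yellow,
2 red, −1 white. (Portal prose sometimes describes heterozygous as gray;
the figure-accurate yellow is used.)

## Concordance categories

The five-category classification of common positions is defined on allele
sets: with REF equal, equal biallelic ALT sets are (i); equal multiallelic
ALT sets (ii); overlapping-but-unequal sets with at least one side
multiallelic (iii); unequal biallelic (iv); disjoint with at least one side
multiallelic (v). A REF mismatch at a common position is classified (iv or
v by allelism), not dropped, mirroring positional diff semantics; the
report additionally counts common positions whose REF alleles agree. The
summary ratio is reproduced exactly as portals print it,
(iii+iv+v)/(i+ii+iii) — note (iii) appears in both numerator and
denominator by that convention — as an exact rational rounded to three
decimals, NA when the denominator is zero.

Genotype discordance profiles compare unordered allele-base multisets, so a
remapped allele index (the same base stored under a different ALT position)
never counts as a mismatch; (site, sample) pairs missing on either side are
excluded from numerator and denominator.

## Variation of Information and loci ranking

VI(P, Q) = H(P) + H(Q) − 2·MI(P, Q) with base-2 logs (bits), computed as
2·H(joint) − H(P) − H(Q) so that VI(P, P) is exactly zero in floating
point. VI is a metric on partitions; the suite verifies symmetry, identity
and the triangle inequality exhaustively over all partitions of six
elements into at most three blocks, and the information bounds
MI ≤ min(H(P), H(Q)), VI ≤ H(P)+H(Q) ≤ 2 log₂ n on random partitions.

Loci ranking scores every subset of 1..k_max loci: SNPs inside the subset's
regions (polymorphic among the labelled samples) feed 1−IBS distances,
complete-linkage clustering into K clusters (default 2), and VI against the
use-type label partition; only labelled samples participate. Subsets with
zero polymorphic SNPs get VI = NA and rank last. Ties break by subset size
then lexicographic locus names. Base-2 logs and complete linkage are
defaults because they are deterministic and reproducible; both are exposed
as options since external clustering tools do not document their exact
settings.

Batch independence is the plain Pearson chi-square on the cluster × source
contingency table, df = (r−1)(c−1), no continuity correction (the
correction choice is stated in the output). Zero cells and expected counts
below 5 are reported as warnings: merging batches is only advisable when
every source has every cluster represented.

## HDF5 store

One group per dataset, one subgroup per chromosome: int8 code matrix
chunked samples × 4096 sites with gzip level 4 (region queries read
contiguous column blocks), position vector, REF/ALT string arrays, synonymy
flag vector; sample names stored once per dataset, and a JSON manifest in a
root attribute. Site identity for cross-dataset combination is
(chrom, pos, ref): positions are reference-anchored, ALT lists may differ
between callsets and are merged preserving first-seen order; a REF conflict
at one position is an error. Duplicate sample names across combined
datasets become `name@dataset`. The "highlight nonsynonymous" display
option returns the same site set as "all" (flags populated); "nonsynonymous
only" restricts the site set. Allele-value constraints match on the
genotype code at the constraint position; missing never matches. PLINK
export uses the text `.ped`/`.map` dialect (self-describing and diffable);
Flapjack uses the `# fjFile = MAP` / `# fjFile = GENOTYPE` headers with
bases, `ref/alt` heterozygotes and empty missing cells.

## Synthetic data

`simulate_genotypes` draws, per site with alternate frequency p (fixed or
uniform on an interval) and inbreeding coefficient F, genotypes with
probabilities (q² + Fpq, 2pq(1−F), p² + Fpq), then masks entries at the
missing rate. `simulate_labelled_blocks` overlays group-canonical
haplotype blocks (all hom-ref vs all hom-alt) on such a background; each
sample carries its own group's block with the locus' association
probability, so association 1.0 separates groups perfectly and 0.5 is
uninformative. `simulate_paired_vcfs` inverts the concordance classifier:
it emits site pairs realizing prescribed category counts, and
classification recovers those counts exactly. All generators are pure
functions of their spec including a mandatory seed (no global random
state); sites sit on one synthetic chromosome at 100 bp spacing by default,
which makes LD-window behavior in tests predictable.

What the generators do not emulate: linkage disequilibrium decay and
recombination (background sites are independent), allele-frequency spectra
of real populations, sequencing-depth or ascertainment structure, batch
artifacts, and indel/complex alleles. Passing tests therefore demonstrate
the correctness of the algorithms and file formats on controlled inputs,
not robustness to every pathology of real resequencing data.

## Problem sizes and determinism

The test and demonstration workloads are deliberately small — hundreds of
samples and tens to hundreds of sites — chosen so exact and enumeration
oracles (rational-arithmetic HWE, exhaustive VI metric checks, additive-
metric NJ recovery up to 12 leaves, 2000-sample parameter recovery at 3σ)
are feasible; the algorithms themselves stream or scale as O(samples ×
sites) and the store is chunked for larger matrices. All randomness flows
through explicit seeds; repeated runs are byte-identical.

## Known limitations

- No phasing, genotype likelihoods, or haplotype-EM LD.
- Indels are classified and filtered but not given concordance categories
  of their own; the five categories are defined for SNP-site comparison.
- The exact HWE test is uncorrected; tools applying mid-p corrections will
  report systematically smaller p-values near the boundary.
- MDS substitutes 1−IBS for externally estimated IBD (see above).
- The store is single-reference; no lift-over between references.
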