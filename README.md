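# snpdesk

A desk-scale toolkit for managing and analysing multi-sample SNP callsets,
built around the workflow of crop genotype portals: ingest VCF into a
queryable genotype-matrix store, recompute per-site QC tags, compare
callsets, cluster haplotypes, build diversity trees and MDS plots, and rank
gene-locus combinations by how well their SNP clustering matches sample
use-type labels (e.g. hemp vs drug type in *Cannabis sativa*).

It is aimed at researchers who work with consolidated public genotyping
data — whole-genome resequencing, RNA-Seq-derived and amplicon callsets
against one reference — and need reproducible, scriptable versions of the
operations a genotype-portal UI performs, without a database server.

## What it computes

**Genotype matrix.** Diploid genotypes are coded per sample × site as
0 = homozygous reference, 1 = heterozygous, 2 = homozygous alternate,
−1 = missing (half-calls are treated as missing; multiallelic alternates
collapse to a single alternate state for coding, while the site index keeps
the full allele list). Matrices are stored per dataset/chromosome in HDF5
with region query, union/intersection combination across datasets, and
export to CSV/TSV, PLINK `.ped`/`.map` and Flapjack formats.

**Per-site QC.** Call rate, `F_MISSING`, allele frequencies, MAF, fraction
heterozygous, mean depth, QUAL, and the exact conditional Hardy–Weinberg
test on genotype counts (Levene–Haldane): `HWE` is the two-sided p-value
(sum of heterozygote counts no more probable than observed), `ExcHet` the
one-sided excess-heterozygosity tail P(het ≥ observed). Sites can be
filtered with bcftools-style expressions such as
`(F_MISSING<0.5 & MAF>0.2 & QUAL>100000 & (ExcHet>0.5 | HWE>0.5))`
and LD-pruned greedily at a genotype-r² threshold within a bp window.

**Callset concordance.** Two position-sorted callsets are merge-joined on
(chrom, pos); common sites fall into five allele-set categories —
(i) biallelic concordant, (ii) multiallelic concordant, (iii) multiallelic
partial concordant, (iv) biallelic discordant, (v) multiallelic
discordant — and summarised by the discordant/concordant ratio
(iii+iv+v)/(i+ii+iii), plus per-site and per-sample genotype discordance
profiles.

**Distances, trees, MDS.** Hamming-fraction and 1−IBS distances over
jointly called sites; hierarchical clustering (average/complete linkage)
with deterministic leaf order and exact K-cluster cuts; Saitou–Nei neighbor
joining with Newick output; classical (Torgerson) MDS.

**Partition comparison.** Variation of Information
VI(P, Q) = H(P) + H(Q) − 2·MI(P, Q) in bits; exhaustive ranking of 1..k
locus combinations by VI between SNP clustering and use-type labels; and a
pre-merge chi-square check that genotype clusters are independent of data
source.

**Synthetic data.** Deterministic generators for inbreeding-model
populations, label-correlated haplotype blocks and paired callsets with
prescribed concordance category counts, so everything above runs without
downloading any data.

## Worked example

```sh
snpdesk simulate population --samples 12 --sites 40 --seed 7 --out pop.vcf
snpdesk build pop.vcf --out store.h5 --dataset pop
snpdesk query store.h5 --dataset pop --chrom chrS --start 1 --end 5000 \
    --format csv --out matrix
snpdesk simulate paired --counts 4,1,2,1,1 --unique-a 2 --unique-b 1 \
    --seed 3 --out-a a.vcf --out-b b.vcf
snpdesk concord --a a.vcf --b b.vcf --out report.tsv
```

The `build` step prints the ingested shape, and `concord` prints the
comparison headline:

```
pop: 12 samples, chrS:40
common=9 ratio=0.571
```

`common=9` is the number of shared positions (4+1+2+1+1 category sites) and
`0.571` the discordant/concordant ratio (2+1+1)/(4+1+2) — the same statistic
the comparison report writes to `report.tsv` together with the five category
counts and per-site/per-sample discordance tables.

Ranking loci against use-type labels:

```sh
snpdesk simulate blocks --groups hemp:20,drug:20 --loci locusA:chrS:1000:2000 \
    --association 1.0 --seed 9 --out blk.vcf --labels-out labels.tsv
printf 'locusA\tchrS\t1000\t2000\nbg\tchrS\t5000\t6000\n' > loci.tsv
snpdesk rankloci blk.vcf --loci loci.tsv --labels labels.tsv --kmax 2 --out rank.tsv
```

`rank.tsv` lists every 1- and 2-locus subset sorted by VI; a perfectly
label-associated locus appears first with `vi = 0` (its K = 2 clustering
reproduces the hemp/drug labelling exactly).

## Layout

- `src/snpdesk/vcf_model.py` — VCF parsing, site classification, SNP
  extraction, genotype encoding
- `src/snpdesk/site_stats.py` — QC tags, exact HWE/ExcHet, filter
  expressions, LD pruning, distribution/curve data
- `src/snpdesk/matrix_store.py` — HDF5 store, region query, combination,
  exports
- `src/snpdesk/cluster_trees.py` — distances, hierarchical clustering,
  neighbor joining, heatmap layout, classical MDS
- `src/snpdesk/concordance.py` — pairwise callset comparison
- `src/snpdesk/partition_match.py` — VI, loci ranking, batch independence
- `src/snpdesk/synth_fixtures.py` — deterministic synthetic generators
- `src/snpdesk/cli.py` — `snpdesk` command-line interface

See `docs/methods.md` for the statistical definitions, defaults and
limitations.
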