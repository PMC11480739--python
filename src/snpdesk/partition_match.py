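"""Variation of Information, loci-combination ranking, batch independence.

Variation of Information (VI) is the information-theoretic metric between two
partitions P and Q of the same sample set:

    VI(P, Q) = H(P) + H(Q) - 2 MI(P, Q)

with entropies and mutual information taken from the joint contingency table
(base-2 logs, so values are in bits; 0 log 0 = 0).  VI = 0 iff the partitions
coincide, and VI = H(P) + H(Q) when they are independent.

``rank_loci_combinations`` scores every 1..k_max-locus subset of a gene-locus
panel by how well SNP clustering within the subset's regions (1-IBS distance,
complete linkage, K clusters) matches a sample use-type labelling — low VI
means a better match.  ``batch_independence`` is the pre-merge chi-square
check that genotype clusters are independent of data source.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.stats import chi2_contingency

from .cluster_trees import Partition, hier_cluster, pairwise_distance
from .errors import DomainError
from .vcf_model import GenotypeMatrix

__all__ = [
    "Locus",
    "VIResult",
    "LociSetScore",
    "Chi2Result",
    "variation_of_information",
    "rank_loci_combinations",
    "batch_independence",
    "read_loci_table",
    "read_two_column_table",
]


@dataclass(frozen=True)
class Locus:
    """A named genomic region, 1-based inclusive coordinates."""

    name: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise DomainError(f"locus {self.name}: start > end")

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


@dataclass(frozen=True)
class VIResult:
    vi: float
    h_p: float
    h_q: float
    mi: float


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def variation_of_information(p: Partition, q: Partition) -> VIResult:
    """VI, both entropies and the mutual information, in bits."""
    if set(p.assignment) != set(q.assignment):
        raise DomainError("partitions must cover the identical sample set")
    samples = sorted(p.assignment)
    pa = np.array([p.assignment[s] for s in samples])
    qa = np.array([q.assignment[s] for s in samples])
    joint = np.zeros((pa.max(), qa.max()))
    for x, y in zip(pa, qa):
        joint[x - 1, y - 1] += 1
    h_p = _entropy(joint.sum(axis=1))
    h_q = _entropy(joint.sum(axis=0))
    # MI via the joint entropy keeps VI(P, P) exactly zero: for identical
    # partitions the joint table's nonzero counts are the marginal counts
    h_joint = _entropy(joint.ravel())
    mi = max(h_p + h_q - h_joint, 0.0)
    vi = max(2.0 * h_joint - h_p - h_q, 0.0)
    return VIResult(vi, h_p, h_q, mi)


@dataclass(frozen=True)
class LociSetScore:
    """One scored locus subset: names, subset size, SNPs used, VI (None = NA)."""

    names: tuple[str, ...]
    k: int
    n_snps: int
    vi: Optional[float]


def _polymorphic_site_indices(matrix: GenotypeMatrix, loci: Sequence[Locus]) -> list[int]:
    idx = []
    for j, site in enumerate(matrix.sites):
        if any(l.contains(site.chrom, site.pos) for l in loci):
            col = matrix.codes[:, j]
            called = col[col >= 0]
            if called.size and np.unique(called).size >= 2:
                idx.append(j)
    return idx


def rank_loci_combinations(
    matrix: GenotypeMatrix,
    loci: Sequence[Locus],
    k_max: int,
    labels: Mapping[str, object],
    k_clusters: int = 2,
    linkage: str = "complete",
    metric: str = "one_minus_ibs",
) -> list[LociSetScore]:
    """Rank all 1..k_max locus subsets by VI against a use-type labelling.

    Only labelled samples are used.  A subset with zero polymorphic SNPs in
    its regions among the labelled samples gets VI = NA and ranks last.
    Output is sorted ascending by VI, ties broken by (subset size,
    lexicographic locus names).
    """
    if not loci:
        raise DomainError("empty loci list")
    names = [l.name for l in loci]
    if len(set(names)) != len(names):
        raise DomainError("locus names must be unique")
    labelled = [s for s in matrix.samples if s in labels]
    if len(labelled) < max(2, k_clusters):
        raise DomainError("need at least k_clusters labelled samples")
    sub = matrix.take_samples(labelled)
    label_partition = Partition.from_labels({s: labels[s] for s in labelled})
    scores: list[LociSetScore] = []
    for k in range(1, k_max + 1):
        for combo in itertools.combinations(sorted(loci, key=lambda l: l.name), k):
            idx = _polymorphic_site_indices(sub, combo)
            combo_names = tuple(l.name for l in combo)
            if not idx:
                scores.append(LociSetScore(combo_names, k, 0, None))
                continue
            region = sub.take_sites(idx)
            d = pairwise_distance(region, metric=metric)
            _, _, part = hier_cluster(d, linkage=linkage, k=k_clusters)
            vi = variation_of_information(part, label_partition).vi
            scores.append(LociSetScore(combo_names, k, len(idx), vi))
    scores.sort(
        key=lambda s: (s.vi is None, s.vi if s.vi is not None else 0.0, s.k, s.names)
    )
    return scores


@dataclass
class Chi2Result:
    """Pearson chi-square independence test on a cluster x source table."""

    chi2: float
    df: int
    p: float
    table: np.ndarray
    row_labels: list[str]
    col_labels: list[str]
    warnings: list[str]


def batch_independence(
    cluster_partition: Partition, sources: Mapping[str, object]
) -> Chi2Result:
    """Chi-square test that genotype clusters are independent of data source.

    Uses the plain Pearson statistic (no continuity correction) with
    df = (r - 1)(c - 1).  Zero cells and expected counts below 5 are reported
    as warnings — merging batches is only advisable when every source has
    every cluster represented.
    """
    samples = [s for s in cluster_partition.assignment if s in sources]
    if not samples:
        raise DomainError("no samples shared between partition and sources")
    clusters = sorted({cluster_partition.assignment[s] for s in samples})
    srcs = sorted({str(sources[s]) for s in samples})
    if len(clusters) < 2 or len(srcs) < 2:
        raise DomainError("need at least 2 clusters and 2 sources")
    table = np.zeros((len(clusters), len(srcs)), dtype=int)
    ci = {c: i for i, c in enumerate(clusters)}
    si = {c: i for i, c in enumerate(srcs)}
    for s in samples:
        table[ci[cluster_partition.assignment[s]], si[str(sources[s])]] += 1
    chi2, p, df, expected = chi2_contingency(table, correction=False)
    warns = []
    for (r, c), v in np.ndenumerate(table):
        if v == 0:
            warns.append(f"zero cell: source {srcs[c]!r} has no cluster {clusters[r]}")
    if (expected < 5).any():
        warns.append("some expected counts are < 5; chi-square approximation is weak")
    return Chi2Result(
        float(chi2), int(df), float(p),
        table, [str(c) for c in clusters], srcs, warns,
    )


def read_loci_table(path) -> list[Locus]:
    """Read a BED-like TSV of loci (name, chrom, start, end; 1-based inclusive)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            name, chrom, start, end = line.split("\t")[:4]
            out.append(Locus(name, chrom, int(start), int(end)))
    return out


def read_two_column_table(path) -> dict[str, str]:
    """Read a two-column TSV (sample, value): use-type labels or data sources."""
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            key, value = line.split("\t")[:2]
            out[key] = value
    return out
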