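"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pytest

from snpdesk.vcf_model import GenotypeMatrix, SiteEntry


TOY_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=chr1,length=100000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2
chr1\t100\t.\tA\tG\t50\t.\t.\tGT:DP\t0/1:10\t1/1:5
chr1\t200\t.\tA\tG,T\t60\t.\t.\tGT:DP\t0/2:7\t./.:.
chr1\t300\t.\tC\tT\t.\t.\t.\tGT:DP\t1|0:3\t./0:2
"""


@pytest.fixture
def toy_vcf(tmp_path):
    path = tmp_path / "toy.vcf"
    path.write_text(TOY_VCF)
    return path


@pytest.fixture
def toy_matrix():
    """3 samples x 4 biallelic sites with one missing cell."""
    sites = [
        SiteEntry("chr1", 100, "A", ("G",)),
        SiteEntry("chr1", 200, "C", ("T",)),
        SiteEntry("chr1", 300, "G", ("A",)),
        SiteEntry("chr2", 50, "T", ("C",)),
    ]
    codes = np.array(
        [
            [0, 1, 2, 0],
            [1, 2, 2, -1],
            [2, 0, 0, 1],
        ],
        dtype=np.int8,
    )
    return GenotypeMatrix(["X", "Y", "Z"], sites, codes)


def hwe_oracle(n_hom_ref: int, n_het: int, n_hom_alt: int) -> tuple[float, float]:
    """Brute-force Levene-Haldane enumeration in exact rational arithmetic.

    Enumerates every heterozygote count compatible with the conditioned
    allele counts, with probability
    N! / (nAA! nAa! naa!) * 2^nAa * nA! na! / (2N)!
    and returns the two-sided (sum of outcomes no more probable than the
    observed) and upper-tail p-values.
    """
    n = n_hom_ref + n_het + n_hom_alt
    n_a = 2 * n_hom_ref + n_het
    n_b = 2 * n_hom_alt + n_het
    if n_a == 0 or n_b == 0:
        return 1.0, 1.0
    f = math.factorial
    dist: dict[int, Fraction] = {}
    n_rare = min(n_a, n_b)
    for h in range(n_rare % 2, n_rare + 1, 2):
        n_rr = (n_rare - h) // 2
        n_cc = n - n_rr - h
        dist[h] = (
            Fraction(f(n), f(n_rr) * f(h) * f(n_cc))
            * Fraction(2**h)
            * Fraction(f(n_a) * f(n_b), f(2 * n))
        )
    total = sum(dist.values())
    assert total == 1
    p_obs = dist[n_het]
    hwe_p = float(sum(p for p in dist.values() if p <= p_obs))
    exchet_p = float(sum(p for h, p in dist.items() if h >= n_het))
    return hwe_p, exchet_p


def random_additive_tree(rng: np.random.Generator, n_leaves: int):
    """Random binary topology with positive branch lengths + leaf distances.

    Returns (newick string, labels, distance matrix).  Distances are computed
    independently of any tree code in the package, by path lengths between
    leaves in an explicit parent map.
    """
    # start with leaves, repeatedly join two random subtrees
    nodes = list(range(n_leaves))
    parent: dict[int, tuple[int, float]] = {}
    next_id = n_leaves
    active = nodes[:]
    while len(active) > 1:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[i], active[j]
        for child in (a, b):
            parent[child] = (next_id, float(rng.uniform(0.05, 1.0)))
        active = [x for x in active if x not in (a, b)] + [next_id]
        next_id += 1

    def path_to_root(x: int) -> dict[int, float]:
        out = {x: 0.0}
        acc = 0.0
        while x in parent:
            x, ln = parent[x][0], parent[x][1]
            acc += ln
            out[x] = acc
        return out

    labels = [f"L{i}" for i in range(n_leaves)]
    d = np.zeros((n_leaves, n_leaves))
    paths = [path_to_root(i) for i in range(n_leaves)]
    for i in range(n_leaves):
        for j in range(i + 1, n_leaves):
            shared = set(paths[i]) & set(paths[j])
            dij = min(paths[i][s] + paths[j][s] for s in shared)
            d[i, j] = d[j, i] = dij

    children: dict[int, list[int]] = {}
    for c, (p, _ln) in parent.items():
        children.setdefault(p, []).append(c)

    def newick(x: int) -> str:
        if x < n_leaves:
            body = labels[x]
        else:
            body = "(" + ",".join(newick(c) for c in children[x]) + ")"
        ln = parent[x][1] if x in parent else 0.0
        return f"{body}:{ln:g}"

    root = next_id - 1
    return newick(root) + ";", labels, d


def rf_distance(newick_a: str, newick_b: str) -> float:
    """Robinson-Foulds distance via dendropy (independent tree library)."""
    import dendropy
    from dendropy.calculate import treecompare

    tns = dendropy.TaxonNamespace()
    ta = dendropy.Tree.get(data=newick_a, schema="newick", taxon_namespace=tns)
    tb = dendropy.Tree.get(data=newick_b, schema="newick", taxon_namespace=tns)
    ta.encode_bipartitions()
    tb.encode_bipartitions()
    return treecompare.symmetric_difference(ta, tb, is_bipartitions_updated=True)


def all_partitions(n: int, max_blocks: int):
    """Every partition of range(n) into at most max_blocks blocks.

    Enumerated as restricted-growth strings; yields Partition objects over
    samples e0..e{n-1}.
    """
    from snpdesk.cluster_trees import Partition

    def grow(prefix: list[int]):
        if len(prefix) == n:
            yield prefix[:]
            return
        top = max(prefix) if prefix else 0
        limit = min(top + 1, max_blocks - 1)
        for v in range(limit + 1):
            yield from grow(prefix + [v])

    for rgs in grow([0]):
        yield Partition({f"e{i}": v + 1 for i, v in enumerate(rgs)})
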