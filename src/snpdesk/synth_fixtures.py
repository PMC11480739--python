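"""Deterministic synthetic genotype data for tests and demonstrations.

Three generators cover the data shapes the toolkit consumes, so nothing has
to be downloaded:

* :func:`simulate_genotypes` — a diploid population with per-site alternate
  allele frequency drawn from a sampler and genotype frequencies following
  the inbreeding model (q^2 + Fpq, 2pq(1 - F), p^2 + Fpq) with optional
  missingness;
* :func:`simulate_labelled_blocks` — label-correlated haplotype blocks:
  within associated loci each sample carries its group's canonical haplotype
  with a stated probability, on top of a background population;
* :func:`simulate_paired_vcfs` — the inverse of the concordance classifier:
  two callsets realizing prescribed unique counts and per-category common
  site counts exactly.

Every generator is a pure function of its spec including the mandatory seed:
identical specs give byte-identical files.  Sites are laid on one synthetic
chromosome at fixed 100 bp spacing unless overridden.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .concordance import CATEGORIES, ComparisonSummary
from .errors import DomainError
from .vcf_model import GenotypeMatrix, SiteEntry, VariantSite, write_vcf
from .partition_match import Locus

__all__ = [
    "PopulationSpec",
    "BlockSpec",
    "simulate_genotypes",
    "simulate_labelled_blocks",
    "simulate_paired_vcfs",
    "paired_sites",
]


@dataclass(frozen=True)
class PopulationSpec:
    """Population generator settings.

    ``maf`` is either a fixed alternate-allele frequency in (0, 1) or a
    ``("uniform", lo, hi)`` sampler spec; ``inbreeding`` is Wright's F.
    """

    n_samples: int
    n_sites: int
    seed: int
    maf: "float | tuple" = 0.3
    inbreeding: float = 0.0
    missing_rate: float = 0.0
    chrom: str = "chrS"
    start_pos: int = 100
    spacing: int = 100

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_sites < 1:
            raise DomainError("n_samples and n_sites must be >= 1")
        if not 0.0 <= self.inbreeding <= 1.0:
            raise DomainError("inbreeding F must be in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise DomainError("missing_rate must be in [0, 1)")
        if isinstance(self.maf, (int, float)):
            if not 0.0 < float(self.maf) < 1.0:
                raise DomainError("fixed allele frequency must be in (0, 1)")
        else:
            kind, lo, hi = self.maf
            if kind != "uniform" or not (0.0 <= lo < hi <= 1.0):
                raise DomainError(f"unsupported maf sampler {self.maf!r}")


def _sample_freqs(spec: PopulationSpec, rng: np.random.Generator) -> np.ndarray:
    if isinstance(spec.maf, (int, float)):
        return np.full(spec.n_sites, float(spec.maf))
    _, lo, hi = spec.maf
    return rng.uniform(lo, hi, size=spec.n_sites)


_REF_ALT = ("A", "G")


def _positions(spec: PopulationSpec, n: int) -> np.ndarray:
    return spec.start_pos + spec.spacing * np.arange(n)


def simulate_genotypes(
    spec: PopulationSpec, vcf_path: Optional[str | Path] = None
) -> GenotypeMatrix:
    """Draw a diploid genotype matrix under the inbreeding model.

    Per site with alternate frequency p (q = 1 - p), genotype probabilities
    are (q^2 + Fpq, 2pq(1 - F), p^2 + Fpq); missing entries are masked at the
    missing rate.  Optionally writes the matrix as a VCF.
    """
    rng = np.random.default_rng(spec.seed)
    p = _sample_freqs(spec, rng)
    q = 1.0 - p
    f = spec.inbreeding
    probs = np.stack(
        [q * q + f * p * q, 2 * p * q * (1 - f), p * p + f * p * q], axis=1
    )
    u = rng.random((spec.n_samples, spec.n_sites))
    c1 = probs[:, 0][None, :]
    c2 = (probs[:, 0] + probs[:, 1])[None, :]
    codes = np.where(u < c1, 0, np.where(u < c2, 1, 2)).astype(np.int8)
    if spec.missing_rate > 0:
        miss = rng.random((spec.n_samples, spec.n_sites)) < spec.missing_rate
        codes[miss] = -1
    samples = [f"S{i + 1:04d}" for i in range(spec.n_samples)]
    pos = _positions(spec, spec.n_sites)
    entries = [
        SiteEntry(spec.chrom, int(pp), _REF_ALT[0], (_REF_ALT[1],)) for pp in pos
    ]
    matrix = GenotypeMatrix(samples, entries, codes)
    if vcf_path is not None:
        write_vcf(matrix, vcf_path)
    return matrix


@dataclass(frozen=True)
class BlockSpec:
    """Label-correlated haplotype block generator settings.

    ``groups`` maps a use-type label to its sample count; ``loci`` are
    non-overlapping regions on the background chromosome; ``association``
    maps locus name -> probability that a sample's block haplotype matches
    its own group's canonical haplotype (1.0 = perfect separation, 0.5 =
    uninformative).
    """

    groups: dict[str, int]
    loci: tuple[Locus, ...]
    association: dict[str, float]
    background: PopulationSpec

    def __post_init__(self) -> None:
        if not self.groups or any(n < 1 for n in self.groups.values()):
            raise DomainError("groups must be non-empty")
        if sum(self.groups.values()) != self.background.n_samples:
            raise DomainError("group sizes must sum to background n_samples")
        regions = sorted(self.loci, key=lambda l: (l.chrom, l.start))
        for a, b in zip(regions, regions[1:]):
            if a.chrom == b.chrom and b.start <= a.end:
                raise DomainError(f"loci {a.name} and {b.name} overlap")
        for l in self.loci:
            strength = self.association.get(l.name, 1.0)
            if not 0.0 <= strength <= 1.0:
                raise DomainError("association strength must be in [0, 1]")


def simulate_labelled_blocks(
    spec: BlockSpec,
    vcf_path: Optional[str | Path] = None,
    labels_path: Optional[str | Path] = None,
) -> tuple[GenotypeMatrix, dict[str, str]]:
    """Background population plus group-separating haplotype blocks.

    Group 0's canonical block haplotype is all homozygous-reference, the
    other groups' all homozygous-alternate; per locus, each sample draws one
    whole-block haplotype from its own group with the locus' association
    probability, else from the opposite canonical.
    """
    matrix = simulate_genotypes(spec.background)
    labels: dict[str, str] = {}
    group_of = np.empty(matrix.n_samples, dtype=int)
    i = 0
    for g, (label, count) in enumerate(spec.groups.items()):
        for _ in range(count):
            labels[matrix.samples[i]] = label
            group_of[i] = g
            i += 1
    codes = matrix.codes.copy()
    pos = np.array([e.pos for e in matrix.sites])
    chroms = np.array([e.chrom for e in matrix.sites])
    block_rng = np.random.default_rng((spec.background.seed, 7919))
    for locus in spec.loci:
        strength = spec.association.get(locus.name, 1.0)
        in_region = (chroms == locus.chrom) & (pos >= locus.start) & (pos <= locus.end)
        if not in_region.any():
            continue
        own = block_rng.random(matrix.n_samples) < strength
        # canonical haplotypes: group 0 -> hom-ref, others -> hom-alt
        canonical = np.where(group_of == 0, 0, 2)
        other = np.where(group_of == 0, 2, 0)
        hap = np.where(own, canonical, other).astype(np.int8)
        codes[:, in_region] = hap[:, None]
    out = GenotypeMatrix(matrix.samples, matrix.sites, codes)
    if vcf_path is not None:
        write_vcf(out, vcf_path)
    if labels_path is not None:
        with open(labels_path, "w") as fh:
            for s in out.samples:
                fh.write(f"{s}\t{labels[s]}\n")
    return out, labels


# Allele templates per concordance category: (ref_a, alts_a, ref_b, alts_b)
_CATEGORY_TEMPLATES = {
    "i": ("A", ("G",), "A", ("G",)),
    "ii": ("A", ("G", "T"), "A", ("G", "T")),
    "iii": ("A", ("G", "T"), "A", ("G",)),
    "iv": ("A", ("G",), "A", ("T",)),
    "v": ("A", ("G", "T"), "A", ("C",)),
}


def _site(chrom: str, pos: int, ref: str, alts: tuple[str, ...]) -> VariantSite:
    # two samples, genotypes exercising ref and the first alternate
    return VariantSite(
        chrom=chrom, pos=pos, ref=ref, alts=alts,
        genotypes=((0, 1), (1, 1)), qual=100.0,
    )


def paired_sites(
    counts: dict[str, int],
    unique_a: int = 0,
    unique_b: int = 0,
    seed: int = 0,
    chrom: str = "chrS",
    spacing: int = 100,
) -> tuple[list[VariantSite], list[VariantSite], ComparisonSummary]:
    """In-memory form of :func:`simulate_paired_vcfs` (plus expected summary)."""
    for c in CATEGORIES:
        if counts.get(c, 0) < 0:
            raise DomainError("category counts must be non-negative")
    if unique_a < 0 or unique_b < 0:
        raise DomainError("unique counts must be non-negative")
    slots = (
        ["ua"] * unique_a
        + ["ub"] * unique_b
        + [c for c in CATEGORIES for _ in range(counts.get(c, 0))]
    )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(slots))
    sites_a: list[VariantSite] = []
    sites_b: list[VariantSite] = []
    for slot_pos, slot_idx in enumerate(order):
        kind = slots[slot_idx]
        pos = 100 + spacing * slot_pos
        if kind == "ua":
            sites_a.append(_site(chrom, pos, "A", ("G",)))
        elif kind == "ub":
            sites_b.append(_site(chrom, pos, "A", ("G",)))
        else:
            ref_a, alts_a, ref_b, alts_b = _CATEGORY_TEMPLATES[kind]
            sites_a.append(_site(chrom, pos, ref_a, alts_a))
            sites_b.append(_site(chrom, pos, ref_b, alts_b))
    sites_a.sort(key=lambda s: s.pos)
    sites_b.sort(key=lambda s: s.pos)
    expected = ComparisonSummary(
        unique_a, unique_b, {c: counts.get(c, 0) for c in CATEGORIES},
        common_same_ref=sum(counts.get(c, 0) for c in CATEGORIES),
    )
    return sites_a, sites_b, expected


def simulate_paired_vcfs(
    counts: dict[str, int],
    unique_a: int,
    unique_b: int,
    seed: int,
    path_a: str | Path,
    path_b: str | Path,
    chrom: str = "chrS",
) -> tuple[Path, Path, ComparisonSummary]:
    """Write two VCFs realizing prescribed concordance category counts.

    ``compare_sites`` on the outputs reproduces the requested summary
    exactly; multiallelic genotypes are written with explicit ALT lists so
    re-reading preserves allele identity.
    """
    sites_a, sites_b, expected = paired_sites(counts, unique_a, unique_b, seed, chrom)
    _write_sites_vcf(sites_a, ["SA", "SB"], path_a)
    _write_sites_vcf(sites_b, ["SA", "SB"], path_b)
    return Path(path_a), Path(path_b), expected


def _write_sites_vcf(
    sites: Sequence[VariantSite], samples: Sequence[str], path: str | Path
) -> None:
    import gzip

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(s.chrom for s in sites):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples) + "\n"
        )
        for s in sites:
            gts = "\t".join(
                "./." if g is None else f"{g[0]}/{g[1]}" for g in s.genotypes
            )
            qual = "." if s.qual is None else f"{s.qual:g}"
            fh.write(
                f"{s.chrom}\t{s.pos}\t.\t{s.ref}\t{','.join(s.alts)}\t{qual}\t.\t.\tGT\t{gts}\n"
            )
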