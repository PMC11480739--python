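"""VCF parsing, site classification, SNP extraction and genotype encoding.

The unit of ingestion is :class:`VariantSite` — one VCF record with per-sample
genotypes as pairs of allele indices.  Genotypes are treated as unphased
throughout: ``0/1``, ``1/0`` and ``0|1`` are the same heterozygote.  Half-calls
(``./0``) are conservatively treated as missing, matching call-rate semantics.
Ploidy is fixed at two; haploid calls are doubled (``0`` becomes ``0/0``).

Diploid genotypes are encoded into a samples x sites integer matrix
(:class:`GenotypeMatrix`) with the four states used by the haplotype viewer:
0 = homozygous reference, 1 = heterozygous, 2 = homozygous alternate,
-1 = missing.  Multiallelic alternates collapse to the single "alternate"
state at encoding time only; the site index keeps the full allele list so that
dataset comparison can reason about allele identity.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

from .errors import (
    ConsistencyError,
    OrderingError,
    UnsupportedInputError,
    VcfParseError,
)

__all__ = [
    "VariantSite",
    "SiteClass",
    "SiteEntry",
    "GenotypeMatrix",
    "VcfReader",
    "read_vcf",
    "write_vcf",
    "classify_site",
    "extract_snps",
    "encode_genotypes",
    "read_annotations",
    "CODE_MISSING",
    "CODE_HOM_REF",
    "CODE_HET",
    "CODE_HOM_ALT",
]

CODE_MISSING = -1
CODE_HOM_REF = 0
CODE_HET = 1
CODE_HOM_ALT = 2

Genotype = Optional[tuple[int, int]]


@dataclass(frozen=True)
class VariantSite:
    """One VCF record: position, alleles and per-sample diploid genotypes.

    ``genotypes[k]`` is an unordered pair of allele indices (0 = REF,
    ``i`` >= 1 = ``alts[i-1]``) for sample ``k``, or ``None`` when missing.
    ``depths[k]`` is the per-sample read depth (DP) or ``None``.
    """

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    genotypes: tuple[Genotype, ...]
    qual: Optional[float] = None
    depths: Optional[tuple[Optional[int], ...]] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise VcfParseError(f"position must be >= 1, got {self.pos}")
        if not self.alts:
            raise VcfParseError(f"{self.chrom}:{self.pos}: no alternate alleles")
        if any(a == self.ref for a in self.alts):
            raise VcfParseError(f"{self.chrom}:{self.pos}: ALT equals REF")
        n_alt = len(self.alts)
        for gt in self.genotypes:
            if gt is None:
                continue
            if not all(0 <= a <= n_alt for a in gt):
                raise VcfParseError(
                    f"{self.chrom}:{self.pos}: allele index out of range in {gt}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.genotypes)

    def alleles(self) -> tuple[str, ...]:
        return (self.ref,) + self.alts


@dataclass(frozen=True)
class SiteClass:
    """Variant kind (snp/indel/mixed) and allelism (biallelic/multiallelic)."""

    variant_kind: str
    allelism: str


def classify_site(site: VariantSite) -> SiteClass:
    """Classify a site by allele lengths and by its alternate allele count.

    A site is a SNP iff REF and every ALT are single bases; an indel iff every
    ALT differs in length from REF; mixed otherwise.
    """
    is_snp_alt = [len(site.ref) == 1 and len(a) == 1 for a in site.alts]
    is_len_diff = [len(a) != len(site.ref) for a in site.alts]
    if all(is_snp_alt):
        kind = "snp"
    elif all(is_len_diff):
        kind = "indel"
    else:
        kind = "mixed"
    allelism = "multiallelic" if len(site.alts) >= 2 else "biallelic"
    return SiteClass(kind, allelism)


@dataclass(frozen=True)
class SiteEntry:
    """Site-index entry of a genotype matrix: locus, alleles, synonymy flag."""

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    synonymy: str = "none"  # {"synonymous", "nonsynonymous", "none"}

    @property
    def label(self) -> str:
        return f"{self.chrom}_{self.pos}"

    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.ref)


@dataclass
class GenotypeMatrix:
    """Samples x sites coded genotype table.

    ``codes[i, j]`` holds the state of sample ``samples[i]`` at site
    ``sites[j]``: 0 hom-ref, 1 het, 2 hom-alt, -1 missing.  Sites are sorted
    by (chrom, pos).
    """

    samples: list[str]
    sites: list[SiteEntry]
    codes: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.samples), len(self.sites)):
            raise ConsistencyError(
                f"codes shape {self.codes.shape} != "
                f"({len(self.samples)}, {len(self.sites)})"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ConsistencyError("duplicate sample names")
        bad = ~np.isin(self.codes, (-1, 0, 1, 2))
        if bad.any():
            raise ConsistencyError("genotype codes must be in {-1, 0, 1, 2}")
        keys = [(s.chrom, s.pos) for s in self.sites]
        if keys != sorted(keys):
            raise OrderingError("matrix sites must be sorted by (chrom, pos)")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_index(self, name: str) -> int:
        return self.samples.index(name)

    def take_samples(self, names: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.sample_index(n) for n in names]
        return GenotypeMatrix(list(names), list(self.sites), self.codes[idx, :])

    def take_sites(self, indices: Sequence[int]) -> "GenotypeMatrix":
        indices = list(indices)
        return GenotypeMatrix(
            list(self.samples),
            [self.sites[j] for j in indices],
            self.codes[:, indices],
        )


class VcfReader:
    """Iterable over :class:`VariantSite` with the sample list up front.

    Thin wrapper over cyvcf2 handling plain and bgzipped VCF.  htslib does not
    expose raw line numbers, so parse errors name the file and the 1-based
    record index instead.
    """

    def __init__(self, path: str | Path):
        self.path = str(path)
        try:
            from cyvcf2 import VCF
        except ImportError as exc:  # pragma: no cover
            raise ImportError("cyvcf2 is required to read VCF files") from exc
        try:
            self._vcf = VCF(self.path, gts012=False)
        except Exception as exc:
            raise VcfParseError(f"{self.path}: malformed VCF header: {exc}") from exc
        self.samples: list[str] = list(self._vcf.samples)
        if len(set(self.samples)) != len(self.samples):
            raise VcfParseError(f"{self.path}: duplicate sample names in header")
        formats = self._format_ids()
        if "GT" not in formats:
            raise UnsupportedInputError(
                f"{self.path}: no GT field defined in FORMAT headers"
            )
        self._has_dp = "DP" in formats

    def _format_ids(self) -> set[str]:
        ids = set()
        for h in self._vcf.header_iter():
            try:
                info = h.info()
            except Exception:
                continue
            if info.get("HeaderType") == "FORMAT":
                ids.add(info.get("ID"))
        return ids

    def __iter__(self) -> Iterator[VariantSite]:
        record_no = 0
        it = iter(self._vcf)
        while True:
            record_no += 1
            try:
                rec = next(it)
            except StopIteration:
                return
            except Exception as exc:
                raise VcfParseError(
                    f"{self.path}: parse error at record {record_no}: {exc}"
                ) from exc
            try:
                yield self._to_site(rec)
            except VcfParseError:
                raise
            except Exception as exc:
                raise VcfParseError(
                    f"{self.path}: parse error at record {record_no} "
                    f"({rec.CHROM}:{rec.POS}): {exc}"
                ) from exc

    def _to_site(self, rec) -> VariantSite:
        alts = tuple(rec.ALT)
        if not alts:
            # Monomorphic reference block: represent with a placeholder alt so
            # the record survives; encode step will see all-reference calls.
            raise VcfParseError(f"{rec.CHROM}:{rec.POS}: record has no ALT allele")
        genotypes: list[Genotype] = []
        for g in rec.genotypes:
            alleles = [a for a in g[:-1] if a is not None]
            if len(alleles) == 1:  # haploid call doubled
                alleles = [alleles[0], alleles[0]]
            if len(alleles) != 2 or any(a < 0 for a in alleles):
                genotypes.append(None)  # missing or half-call
            else:
                genotypes.append((alleles[0], alleles[1]))
        depths: Optional[tuple[Optional[int], ...]] = None
        dp = rec.format("DP") if self._has_dp else None
        if dp is not None:
            vals = []
            for row in np.asarray(dp).reshape(len(genotypes), -1):
                v = int(row[0])
                vals.append(v if v >= 0 else None)
            depths = tuple(vals)
        qual = float(rec.QUAL) if rec.QUAL is not None else None
        return VariantSite(
            chrom=rec.CHROM,
            pos=int(rec.POS),
            ref=rec.REF,
            alts=alts,
            genotypes=tuple(genotypes),
            qual=qual,
            depths=depths,
        )


def read_vcf(path: str | Path) -> VcfReader:
    """Open a VCF (plain or bgzipped) for streaming; GT is required."""
    return VcfReader(path)


def _check_sorted(
    site: VariantSite, last: Optional[tuple[str, int]]
) -> tuple[str, int]:
    if last is not None and site.chrom == last[0] and site.pos < last[1]:
        raise OrderingError(
            f"unsorted input: {site.chrom}:{site.pos} after {last[0]}:{last[1]}"
        )
    return (site.chrom, site.pos)


def extract_snps(sites: Iterable[VariantSite]) -> Iterator[VariantSite]:
    """Keep only single-base substitution alleles, mirroring a TYPE="snp" filter.

    Sites mixing SNP and indel alternates drop the indel alternates; genotype
    allele indices are renumbered to the retained list.  A genotype carrying a
    dropped allele becomes missing.  Sites left with no alternates are dropped
    entirely.  Input must be position-sorted per chromosome.
    """
    last: Optional[tuple[str, int]] = None
    for site in sites:
        last = _check_sorted(site, last)
        keep = [
            i
            for i, alt in enumerate(site.alts)
            if len(site.ref) == 1 and len(alt) == 1
        ]
        if not keep:
            continue
        if len(keep) == len(site.alts):
            yield site
            continue
        remap = {0: 0}
        for new_i, old_i in enumerate(keep, start=1):
            remap[old_i + 1] = new_i
        new_gts: list[Genotype] = []
        for gt in site.genotypes:
            if gt is None or gt[0] not in remap or gt[1] not in remap:
                new_gts.append(None)
            else:
                new_gts.append((remap[gt[0]], remap[gt[1]]))
        yield replace(
            site,
            alts=tuple(site.alts[i] for i in keep),
            genotypes=tuple(new_gts),
        )


def _code_genotype(gt: Genotype) -> int:
    if gt is None:
        return CODE_MISSING
    a, b = gt
    if a == 0 and b == 0:
        return CODE_HOM_REF
    if a > 0 and b > 0:
        return CODE_HOM_ALT  # any pair of alternates collapses to one state
    return CODE_HET


def encode_genotypes(
    sites: Sequence[VariantSite],
    samples: Sequence[str],
    annotations: Optional[dict[tuple[str, int, str, str], str]] = None,
) -> GenotypeMatrix:
    """Encode sites into a samples x sites 0/1/2/-1 matrix.

    All sites must carry genotypes for exactly ``samples`` (in order).  The
    optional ``annotations`` map (chrom, pos, ref, alt) -> synonymy flag fills
    the site-index flag column.
    """
    sites = list(sites)
    n = len(samples)
    for s in sites:
        if s.n_samples != n:
            raise ConsistencyError(
                f"{s.chrom}:{s.pos} has {s.n_samples} genotypes, expected {n}"
            )
    order = sorted(range(len(sites)), key=lambda i: (sites[i].chrom, sites[i].pos))
    entries = []
    codes = np.empty((n, len(sites)), dtype=np.int8)
    for j, i in enumerate(order):
        s = sites[i]
        syn = "none"
        if annotations:
            for alt in s.alts:
                syn = annotations.get((s.chrom, s.pos, s.ref, alt), syn)
                if syn != "none":
                    break
        entries.append(SiteEntry(s.chrom, s.pos, s.ref, s.alts, syn))
        codes[:, j] = [_code_genotype(g) for g in s.genotypes]
    return GenotypeMatrix(list(samples), entries, codes)


_CODE_TO_GT = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> Path:
    """Write a biallelic, unphased VCF 4.2 from a genotype matrix.

    Multiallelic sites are written with their full ALT list but heterozygotes
    always use allele 1, so the round trip is exact for biallelic sites (the
    documented contract).
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(s.chrom for s in matrix.sites):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        for j, site in enumerate(matrix.sites):
            gts = "\t".join(_CODE_TO_GT[int(c)] for c in matrix.codes[:, j])
            fh.write(
                f"{site.chrom}\t{site.pos}\t.\t{site.ref}\t"
                f"{','.join(site.alts)}\t.\t.\t.\tGT\t{gts}\n"
            )
    return path


_EFFECT_MAP = {
    "synonymous_variant": "synonymous",
    "stop_retained_variant": "synonymous",
    "missense_variant": "nonsynonymous",
    "stop_gained": "nonsynonymous",
    "stop_lost": "nonsynonymous",
    "start_lost": "nonsynonymous",
}


def read_annotations(path: str | Path) -> dict[tuple[str, int, str, str], str]:
    """Read a tab-delimited SnpEff-like effect table.

    Columns: chrom, pos, ref, alt, effect.  Effects map onto the synonymy flag
    (missense/stop/start changes -> nonsynonymous; synonymous/stop-retained ->
    synonymous; anything else -> none).
    """
    out: dict[tuple[str, int, str, str], str] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise VcfParseError(
                    f"{path}: line {line_no}: expected 5 columns, got {len(parts)}"
                )
            chrom, pos, ref, alt, effect = parts[:5]
            out[(chrom, int(pos), ref, alt)] = _EFFECT_MAP.get(effect, "none")
    return out
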