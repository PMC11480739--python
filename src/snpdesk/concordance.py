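"""Pairwise callset comparison: position partitioning and allele concordance.

Two position-sorted site streams are merge-joined on (chrom, pos).  Unmatched
positions are unique to one set; matched positions fall into five concordance
categories based on the allele sets A = {ref_a} + alts_a and B = {ref_b} +
alts_b:

* i   biallelic concordant      — both biallelic, same REF, same ALT set
* ii  multiallelic concordant   — at least one multiallelic, same REF, same ALT set
* iii multiallelic partial      — at least one multiallelic, same REF, ALT sets
                                  overlap but differ
* iv  biallelic discordant      — both biallelic with differing ALT (or REF)
* v   multiallelic discordant   — at least one multiallelic, ALT sets disjoint
                                  (or REF mismatch)

The summary ratio is (iii + iv + v) / (i + ii + iii), reproduced exactly as
the portal reports it.  Genotype-level discordance profiles compare unordered
allele-base multisets so allele *index* remapping between callsets cannot
create false mismatches.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Iterator, Optional, Sequence

from .errors import DomainError, OrderingError
from .vcf_model import VariantSite

__all__ = [
    "ComparisonSummary",
    "DiscordanceProfile",
    "compare_sites",
    "classify_pair",
    "summary_ratio",
    "shared_fraction",
    "discordance_profiles",
    "CATEGORIES",
]

CATEGORIES = ("i", "ii", "iii", "iv", "v")


@dataclass
class ComparisonSummary:
    """Unique/common position counts and the five concordance categories.

    ``common_same_ref`` additionally counts common positions whose REF alleles
    agree (the position-only join is primary; this is informational).
    """

    unique_a: int
    unique_b: int
    cat: dict[str, int]
    common_same_ref: int = 0

    @property
    def common(self) -> int:
        return sum(self.cat.values())

    @property
    def ratio(self) -> Optional[float]:
        return summary_ratio(self.cat)


def classify_pair(a: VariantSite, b: VariantSite) -> str:
    """Concordance category of two records at the same position."""
    alts_a, alts_b = set(a.alts), set(b.alts)
    multi = len(a.alts) >= 2 or len(b.alts) >= 2
    if a.ref != b.ref:
        return "v" if multi else "iv"
    if not multi:
        return "i" if alts_a == alts_b else "iv"
    if alts_a == alts_b:
        return "ii"
    if alts_a & alts_b:
        return "iii"
    return "v"


def _sorted_stream(
    sites: Iterable[VariantSite], which: str
) -> Iterator[VariantSite]:
    last: Optional[tuple[str, int]] = None
    for site in sites:
        if last is not None and site.chrom == last[0] and site.pos < last[1]:
            raise OrderingError(
                f"stream {which}: {site.chrom}:{site.pos} after {last[0]}:{last[1]}"
            )
        last = (site.chrom, site.pos)
        yield site


def compare_sites(
    a: Iterable[VariantSite],
    b: Iterable[VariantSite],
    collect_labels: bool = True,
) -> tuple[ComparisonSummary, list[tuple[str, int, str]]]:
    """Merge-join two sorted site streams and classify common positions.

    Returns the summary plus, when ``collect_labels``, a list of
    (chrom, pos, category) for every common position.
    """
    # Index stream b once; streams are desk-scale (memory O(|b|)).
    b_index: dict[tuple[str, int], VariantSite] = {}
    for site in _sorted_stream(b, "b"):
        b_index[(site.chrom, site.pos)] = site
    cat = {c: 0 for c in CATEGORIES}
    unique_a = 0
    same_ref = 0
    labels: list[tuple[str, int, str]] = []
    matched: set[tuple[str, int]] = set()
    for site in _sorted_stream(a, "a"):
        key = (site.chrom, site.pos)
        other = b_index.get(key)
        if other is None:
            unique_a += 1
            continue
        matched.add(key)
        c = classify_pair(site, other)
        cat[c] += 1
        if site.ref == other.ref:
            same_ref += 1
        if collect_labels:
            labels.append((site.chrom, site.pos, c))
    unique_b = len(b_index) - len(matched)
    return ComparisonSummary(unique_a, unique_b, cat, same_ref), labels


def summary_ratio(cat: "dict[str, int] | Sequence[int]") -> Optional[float]:
    """Discordant/concordant ratio (iii + iv + v) / (i + ii + iii), 3 decimals.

    Returns ``None`` (NA) when the denominator is zero.  Computed as an exact
    rational before rounding.
    """
    if not isinstance(cat, dict):
        counts = list(cat)
        if len(counts) != 5:
            raise DomainError("expected five category counts")
        cat = dict(zip(CATEGORIES, counts))
    if any(cat[c] < 0 for c in CATEGORIES):
        raise DomainError("category counts must be non-negative")
    num = cat["iii"] + cat["iv"] + cat["v"]
    den = cat["i"] + cat["ii"] + cat["iii"]
    if den == 0:
        return None
    return float(round(Fraction(num, den), 3))


def shared_fraction(summary: ComparisonSummary, side: str) -> float:
    """Fraction of one set's positions found in the other (common / set total)."""
    if side == "a":
        total = summary.unique_a + summary.common
    elif side == "b":
        total = summary.unique_b + summary.common
    else:
        raise DomainError("side must be 'a' or 'b'")
    if total == 0:
        raise DomainError("empty position set")
    return summary.common / total


@dataclass
class DiscordanceProfile:
    """Genotype discordance fractions by common site and by shared sample."""

    by_site: dict[tuple[str, int], float]
    by_sample: dict[str, float]


def _genotype_bases(site: VariantSite, sample_idx: int) -> Optional[tuple[str, str]]:
    gt = site.genotypes[sample_idx]
    if gt is None:
        return None
    alleles = site.alleles()
    pair = sorted((alleles[gt[0]], alleles[gt[1]]))
    return (pair[0], pair[1])


def discordance_profiles(
    a: Iterable[VariantSite],
    a_samples: Sequence[str],
    b: Iterable[VariantSite],
    b_samples: Sequence[str],
    shared_samples: Optional[Sequence[str]] = None,
) -> DiscordanceProfile:
    """Per-site and per-sample genotype discordance over common positions.

    Genotypes are compared as unordered allele-base pairs; (site, sample)
    pairs with a missing genotype on either side are excluded from both the
    numerator and the denominator.
    """
    if shared_samples is None:
        shared_samples = [s for s in a_samples if s in set(b_samples)]
    if not shared_samples:
        raise DomainError("no shared samples between the two callsets")
    for s in shared_samples:
        if s not in a_samples or s not in b_samples:
            raise DomainError(f"sample {s!r} absent from one input")
    ia = [list(a_samples).index(s) for s in shared_samples]
    ib = [list(b_samples).index(s) for s in shared_samples]
    b_index = {(s.chrom, s.pos): s for s in _sorted_stream(b, "b")}
    site_mismatch: dict[tuple[str, int], list[int]] = {}
    samp_counts = {s: [0, 0] for s in shared_samples}  # [mismatches, compared]
    for site in _sorted_stream(a, "a"):
        other = b_index.get((site.chrom, site.pos))
        if other is None:
            continue
        mm, tot = 0, 0
        for s, ai, bi in zip(shared_samples, ia, ib):
            ga = _genotype_bases(site, ai)
            gb = _genotype_bases(other, bi)
            if ga is None or gb is None:
                continue
            tot += 1
            diff = ga != gb
            mm += diff
            samp_counts[s][0] += diff
            samp_counts[s][1] += 1
        site_mismatch[(site.chrom, site.pos)] = [mm, tot]
    by_site = {
        key: (mm / tot if tot else 0.0) for key, (mm, tot) in site_mismatch.items()
    }
    by_sample = {
        s: (mm / tot if tot else 0.0) for s, (mm, tot) in samp_counts.items()
    }
    return DiscordanceProfile(by_site, by_sample)
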