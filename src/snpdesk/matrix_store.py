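"""HDF5 genotype-matrix store: build, region query, set combination, export.

Layout: one HDF5 group per dataset, one subgroup per chromosome, each holding
the samples x sites int8 code matrix (chunked along sites, gzip level 4 so
region queries read contiguous column blocks), the position vector, REF/ALT
string arrays and a synonymy flag vector.  Sample names are stored once per
dataset.  A JSON manifest is embedded as a root attribute and returned.

Site identity for cross-dataset combination is (chrom, pos, ref): positions
are reference-anchored while ALT lists may differ between callsets and are
merged preserving first-seen order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import h5py
import numpy as np

from .errors import ConsistencyError, DomainError, OrderingError
from .vcf_model import GenotypeMatrix, SiteEntry, read_vcf

__all__ = [
    "StoreManifest",
    "RegionQuery",
    "build_store",
    "query",
    "combine",
    "export_matrix",
    "import_matrix",
]

_SYN_CODE = {"none": 0, "synonymous": 1, "nonsynonymous": 2}
_SYN_NAME = {v: k for k, v in _SYN_CODE.items()}

_CHUNK_SITES = 4096


@dataclass
class StoreManifest:
    """Datasets, samples and per-chromosome site counts of a store."""

    reference_name: str
    datasets: dict[str, dict] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"reference_name": self.reference_name, "datasets": self.datasets}
        )

    @classmethod
    def from_json(cls, text: str) -> "StoreManifest":
        obj = json.loads(text)
        return cls(obj["reference_name"], obj["datasets"])


@dataclass
class RegionQuery:
    """Region query: datasets, chromosome span, sample/synonymy/allele filters.

    ``allele_constraints`` is a list of (position, required code); samples
    whose code at a constraint position differs are dropped (missing never
    matches).  ``synonymy`` is one of ``all``, ``highlight_nonsyn`` (same site
    set as ``all``; flags populated for display) or ``nonsyn_only``.
    """

    datasets: list[str]
    chrom: str
    start: int
    end: int
    samples: Optional[list[str]] = None
    synonymy: str = "all"
    allele_constraints: list[tuple[int, int]] = field(default_factory=list)
    combine_mode: str = "union"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise DomainError("query start must be <= end")
        if self.synonymy not in ("all", "highlight_nonsyn", "nonsyn_only"):
            raise DomainError(f"unknown synonymy filter {self.synonymy!r}")
        if self.combine_mode not in ("union", "intersection"):
            raise DomainError(f"unknown combine mode {self.combine_mode!r}")
        for pos, _code in self.allele_constraints:
            if not self.start <= pos <= self.end:
                raise DomainError(f"constraint position {pos} outside query region")


def build_store(
    vcf_path: str | Path,
    out_path: str | Path,
    dataset: str = "default",
    annotations: Optional[dict[tuple[str, int, str, str], str]] = None,
    reference_name: str = "reference",
    append: bool = False,
) -> StoreManifest:
    """Ingest a position-sorted VCF into an HDF5 store (one dataset group).

    Call again with ``append=True`` and a new ``dataset`` name to add further
    datasets to the same container.
    """
    reader = read_vcf(vcf_path)
    samples = reader.samples
    if len(set(samples)) != len(samples):
        raise ConsistencyError("duplicate sample names in VCF")
    from .vcf_model import encode_genotypes

    by_chrom: dict[str, list] = {}
    last: Optional[tuple[str, int]] = None
    for site in reader:
        if last is not None and site.chrom == last[0] and site.pos < last[1]:
            raise OrderingError(
                f"unsorted VCF: {site.chrom}:{site.pos} after {last[0]}:{last[1]}"
            )
        last = (site.chrom, site.pos)
        by_chrom.setdefault(site.chrom, []).append(site)

    mode = "a" if append else "w"
    manifest = StoreManifest(reference_name)
    with h5py.File(out_path, mode) as h5:
        if append and "manifest" in h5.attrs:
            manifest = StoreManifest.from_json(h5.attrs["manifest"])
        if dataset in manifest.datasets:
            raise ConsistencyError(f"dataset {dataset!r} already in store")
        grp = h5.create_group(dataset)
        str_dt = h5py.string_dtype()
        grp.create_dataset("samples", data=np.array(samples, dtype=object), dtype=str_dt)
        chrom_info = {}
        for chrom, sites in by_chrom.items():
            sub = encode_genotypes(sites, samples, annotations)
            cg = grp.create_group(chrom)
            n_sites = sub.n_sites
            chunk = (len(samples), min(_CHUNK_SITES, n_sites))
            cg.create_dataset(
                "codes", data=sub.codes, chunks=chunk, compression="gzip",
                compression_opts=4,
            )
            cg.create_dataset("pos", data=np.array([s.pos for s in sub.sites], dtype=np.int64))
            cg.create_dataset(
                "ref", data=np.array([s.ref for s in sub.sites], dtype=object), dtype=str_dt
            )
            cg.create_dataset(
                "alt",
                data=np.array([",".join(s.alts) for s in sub.sites], dtype=object),
                dtype=str_dt,
            )
            cg.create_dataset(
                "syn",
                data=np.array([_SYN_CODE[s.synonymy] for s in sub.sites], dtype=np.int8),
            )
            chrom_info[chrom] = n_sites
        manifest.datasets[dataset] = {"samples": samples, "chromosomes": chrom_info}
        h5.attrs["manifest"] = manifest.to_json()
    return manifest


def read_manifest(store_path: str | Path) -> StoreManifest:
    with h5py.File(store_path, "r") as h5:
        return StoreManifest.from_json(h5.attrs["manifest"])


def _query_one(h5: h5py.File, dataset: str, q: RegionQuery) -> GenotypeMatrix:
    if dataset not in h5:
        raise KeyError(f"unknown dataset {dataset!r}")
    grp = h5[dataset]
    samples = [s.decode() if isinstance(s, bytes) else s for s in grp["samples"][()]]
    if q.chrom not in grp:
        known = [k for k in grp.keys() if k != "samples"]
        raise KeyError(f"unknown chromosome {q.chrom!r} (have {known})")
    cg = grp[q.chrom]
    pos = cg["pos"][()]
    lo = int(np.searchsorted(pos, q.start, side="left"))
    hi = int(np.searchsorted(pos, q.end, side="right"))
    codes = cg["codes"][:, lo:hi]
    refs = [r.decode() if isinstance(r, bytes) else r for r in cg["ref"][lo:hi]]
    alts = [a.decode() if isinstance(a, bytes) else a for a in cg["alt"][lo:hi]]
    syn = cg["syn"][lo:hi]
    entries = [
        SiteEntry(q.chrom, int(p), r, tuple(a.split(",")), _SYN_NAME[int(s)])
        for p, r, a, s in zip(pos[lo:hi], refs, alts, syn)
    ]
    matrix = GenotypeMatrix(samples, entries, codes)
    if q.samples is not None:
        keep = [s for s in q.samples if s in samples]
        matrix = matrix.take_samples(keep)
    if q.synonymy == "nonsyn_only":
        idx = [j for j, e in enumerate(matrix.sites) if e.synonymy == "nonsynonymous"]
        matrix = matrix.take_sites(idx)
    for cpos, code in q.allele_constraints:
        js = [j for j, e in enumerate(matrix.sites) if e.pos == cpos]
        if not js:
            continue
        mask = np.ones(matrix.n_samples, dtype=bool)
        for j in js:
            mask &= matrix.codes[:, j] == code
        matrix = matrix.take_samples([s for s, m in zip(matrix.samples, mask) if m])
    return matrix


def query(store_path: str | Path, q: RegionQuery) -> GenotypeMatrix:
    """Run a region query; multiple datasets are combined per ``combine_mode``."""
    if not q.datasets:
        raise DomainError("query needs at least one dataset")
    with h5py.File(store_path, "r") as h5:
        parts = [_query_one(h5, ds, q) for ds in q.datasets]
    if len(parts) == 1:
        return parts[0]
    return combine(parts, q.combine_mode, names=q.datasets)


def combine(
    matrices: Sequence[GenotypeMatrix],
    mode: str = "union",
    names: Optional[Sequence[str]] = None,
) -> GenotypeMatrix:
    """Concatenate sample rows; site columns are the union or intersection.

    Site identity is (chrom, pos, ref); two sites at one position with
    different REF raise a consistency error.  Union fills absent cells with
    missing (-1) and merges ALT lists preserving first-seen order; duplicate
    sample names across inputs are disambiguated as ``name@dataset``.
    """
    if mode not in ("union", "intersection"):
        raise DomainError(f"unknown combine mode {mode!r}")
    if not matrices:
        raise DomainError("no matrices to combine")
    if names is None:
        names = [f"ds{i + 1}" for i in range(len(matrices))]
    ref_at: dict[tuple[str, int], str] = {}
    for m in matrices:
        for e in m.sites:
            prev = ref_at.setdefault((e.chrom, e.pos), e.ref)
            if prev != e.ref:
                raise ConsistencyError(
                    f"conflicting REF at {e.chrom}:{e.pos}: {prev!r} vs {e.ref!r}"
                )
    key_sets = [{e.key() for e in m.sites} for m in matrices]
    if mode == "union":
        keys = set().union(*key_sets)
    else:
        keys = set.intersection(*key_sets)
    # merged ALT lists and synonymy, first-seen order/flag wins
    alts: dict[tuple, list[str]] = {k: [] for k in keys}
    syn: dict[tuple, str] = {}
    for m in matrices:
        for e in m.sites:
            k = e.key()
            if k not in keys:
                continue
            for a in e.alts:
                if a not in alts[k]:
                    alts[k].append(a)
            if syn.get(k, "none") == "none" and e.synonymy != "none":
                syn[k] = e.synonymy
    sorted_keys = sorted(keys, key=lambda k: (k[0], k[1]))
    col = {k: j for j, k in enumerate(sorted_keys)}
    seen: dict[str, int] = {}
    out_samples: list[str] = []
    for m, tag in zip(matrices, names):
        for s in m.samples:
            if s in seen or any(s in other.samples for other in matrices if other is not m):
                out_samples.append(f"{s}@{tag}")
            else:
                out_samples.append(s)
            seen[s] = seen.get(s, 0) + 1
    if len(set(out_samples)) != len(out_samples):
        raise ConsistencyError("sample names not unique even after dataset suffixing")
    codes = np.full((len(out_samples), len(sorted_keys)), -1, dtype=np.int8)
    row = 0
    for m in matrices:
        cols = [col[e.key()] for e in m.sites if e.key() in col]
        src = [j for j, e in enumerate(m.sites) if e.key() in col]
        codes[row : row + m.n_samples, cols] = m.codes[:, src]
        row += m.n_samples
    entries = [
        SiteEntry(k[0], k[1], k[2], tuple(alts[k]), syn.get(k, "none"))
        for k in sorted_keys
    ]
    return GenotypeMatrix(out_samples, entries, codes)


_CODE_TO_TEXT = {0: "0", 1: "1", 2: "2", -1: "NA"}
_TEXT_TO_CODE = {v: k for k, v in _CODE_TO_TEXT.items()}


def export_matrix(
    matrix: GenotypeMatrix, format: str, out_prefix: str | Path
) -> list[Path]:
    """Write a genotype matrix as csv, tsv, plink (.ped/.map) or flapjack.

    plink uses the text .ped/.map dialect with the first alternate as the
    "alt" allele; flapjack writes a ``# fjFile = MAP`` map and a
    ``# fjFile = GENOTYPE`` genotype file with bases, het as ``ref/alt``,
    missing empty.
    """
    if matrix.n_samples == 0:
        raise DomainError("matrix has no samples")
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    if format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        path = out_prefix.with_suffix("." + format)
        with open(path, "w") as fh:
            fh.write(sep.join(["sample"] + [e.label for e in matrix.sites]) + "\n")
            for i, s in enumerate(matrix.samples):
                cells = [_CODE_TO_TEXT[int(c)] for c in matrix.codes[i]]
                fh.write(sep.join([s] + cells) + "\n")
        return [path]
    if format == "plink":
        ped = out_prefix.with_suffix(".ped")
        pmap = out_prefix.with_suffix(".map")
        with open(pmap, "w") as fh:
            for e in matrix.sites:
                fh.write(f"{e.chrom}\t{e.label}\t0\t{e.pos}\n")
        with open(ped, "w") as fh:
            for i, s in enumerate(matrix.samples):
                fields = [s, s, "0", "0", "0", "-9"]
                for j, e in enumerate(matrix.sites):
                    ref, alt = e.ref, e.alts[0]
                    code = int(matrix.codes[i, j])
                    pair = {
                        0: (ref, ref),
                        1: (ref, alt),
                        2: (alt, alt),
                        -1: ("0", "0"),
                    }[code]
                    fields.extend(pair)
                fh.write("\t".join(fields) + "\n")
        return [ped, pmap]
    if format == "flapjack":
        fmap = out_prefix.with_suffix(".map")
        geno = out_prefix.with_suffix(".genotype")
        with open(fmap, "w") as fh:
            fh.write("# fjFile = MAP\n")
            for e in matrix.sites:
                fh.write(f"{e.label}\t{e.chrom}\t{e.pos}\n")
        with open(geno, "w") as fh:
            fh.write("# fjFile = GENOTYPE\n")
            fh.write("\t" + "\t".join(e.label for e in matrix.sites) + "\n")
            for i, s in enumerate(matrix.samples):
                cells = []
                for j, e in enumerate(matrix.sites):
                    ref, alt = e.ref, e.alts[0]
                    code = int(matrix.codes[i, j])
                    cells.append({0: ref, 1: f"{ref}/{alt}", 2: alt, -1: ""}[code])
                fh.write(s + "\t" + "\t".join(cells) + "\n")
        return [geno, fmap]
    raise DomainError(f"unsupported export format {format!r}")


def import_matrix(
    format: str,
    prefix: str | Path,
    sites: Optional[Sequence[SiteEntry]] = None,
) -> GenotypeMatrix:
    """Re-read an exported matrix back into codes (round-trip counterpart).

    csv/tsv are self-describing given ``sites`` for the site index; plink and
    flapjack need ``sites`` to map alleles back to codes (their files do not
    record which allele is the reference).
    """
    prefix = Path(prefix)
    if format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        path = prefix.with_suffix("." + format)
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(sep)[1:]
            samples, rows = [], []
            for line in fh:
                parts = line.rstrip("\n").split(sep)
                samples.append(parts[0])
                rows.append([_TEXT_TO_CODE[c] for c in parts[1:]])
        if sites is None:
            sites = []
            for label in header:
                chrom, pos = label.rsplit("_", 1)
                sites.append(SiteEntry(chrom, int(pos), "N", ("N",)))
        return GenotypeMatrix(samples, list(sites), np.array(rows, dtype=np.int8))
    if sites is None:
        raise DomainError(f"{format} import needs the site index to map alleles")
    if format == "plink":
        path = prefix.with_suffix(".ped")
        samples, rows = [], []
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                samples.append(parts[1])
                alleles = parts[6:]
                codes = []
                for j, e in enumerate(sites):
                    a, b = alleles[2 * j], alleles[2 * j + 1]
                    if a == "0" or b == "0":
                        codes.append(-1)
                    else:
                        codes.append((a != e.ref) + (b != e.ref))
                rows.append(codes)
        return GenotypeMatrix(samples, list(sites), np.array(rows, dtype=np.int8))
    if format == "flapjack":
        path = prefix.with_suffix(".genotype")
        samples, rows = [], []
        with open(path) as fh:
            fh.readline()  # fjFile header
            fh.readline()  # marker names
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                samples.append(parts[0])
                codes = []
                for j, e in enumerate(sites):
                    cell = parts[j + 1] if j + 1 < len(parts) else ""
                    if cell == "":
                        codes.append(-1)
                    elif "/" in cell:
                        codes.append(1)
                    elif cell == e.ref:
                        codes.append(0)
                    else:
                        codes.append(2)
                rows.append(codes)
        return GenotypeMatrix(samples, list(sites), np.array(rows, dtype=np.int8))
    raise DomainError(f"unsupported import format {format!r}")
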