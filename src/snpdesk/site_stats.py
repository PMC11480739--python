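"""Per-site QC statistics, filter expressions, LD pruning and plot data.

Recomputes, from genotype codes, the per-site tags a VCF pipeline would add
back after subsetting (call rate, missingness, allele frequencies, fraction
heterozygous, exact Hardy-Weinberg and excess-heterozygosity p-values, mean
depth, QUAL passthrough), evaluates bcftools-style boolean filter expressions
over them, and performs greedy r^2 LD pruning in a base-pair window.

The Hardy-Weinberg test is the exact conditional (Levene-Haldane) test on the
heterozygote count given the allele counts: hwe_p sums the probabilities of
all heterozygote counts no more probable than the observed one (two-sided);
exchet_p is the one-sided upper tail P(het >= observed), i.e. excess
heterozygosity.  No mid-p correction is applied.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import DomainError, FilterParseError
from .vcf_model import GenotypeMatrix

__all__ = [
    "SiteStats",
    "hwe_exact",
    "compute_site_stats",
    "FilterExpression",
    "eval_filter",
    "ld_prune",
    "cumulative_filter_curve",
    "genotype_vs_allele_freq",
    "stats_table",
    "neg_log10",
]

#: floor applied to p-values before -log10 transforms for plotting
P_CLIP = 1e-30


@dataclass(frozen=True)
class SiteStats:
    """Recomputed per-site tags.

    ``af`` is the alternate-allele frequency over non-missing genotypes (all
    alternates collapsed), ``maf = min(af, 1 - af)``, ``frac_het`` the
    heterozygous fraction of non-missing genotypes.  ``hwe_p``/``exchet_p``
    are the exact-test p-values; monomorphic or all-missing sites carry 1.0.
    """

    call_rate: float
    f_missing: float
    af: float
    maf: float
    frac_het: float
    hwe_p: float
    exchet_p: float
    mean_dp: Optional[float] = None
    qual: Optional[float] = None


def _het_log_probs(n_het_obs_parity: int, n_a: int, n_b: int) -> tuple[np.ndarray, np.ndarray]:
    """Support and log-probabilities of the conditional heterozygote count.

    ``n_a``/``n_b`` are the two allele counts (2N total alleles).  The
    heterozygote count shares the parity of min(n_a, n_b).
    """
    n = (n_a + n_b) // 2
    n_rare = min(n_a, n_b)
    hets = np.arange(n_het_obs_parity, n_rare + 1, 2)
    lg = math.lgamma
    logs = np.empty(len(hets), dtype=float)
    const = lg(n + 1) + lg(n_a + 1) + lg(n_b + 1) - lg(2 * n + 1)
    for i, h in enumerate(hets):
        n_rr = (n_rare - h) // 2
        n_cc = n - n_rr - h
        logs[i] = (
            const
            - lg(n_rr + 1)
            - lg(h + 1)
            - lg(n_cc + 1)
            + h * math.log(2.0)
        )
    return hets, logs


def hwe_exact(n_hom_ref: int, n_het: int, n_hom_alt: int) -> tuple[float, float]:
    """Exact conditional HWE test on genotype counts.

    Returns ``(hwe_p, exchet_p)``.  ``hwe_p`` is two-sided (sum of outcomes no
    more probable than observed), ``exchet_p`` the upper tail of the
    heterozygote count.  Monomorphic input returns ``(1.0, 1.0)``.
    """
    for c in (n_hom_ref, n_het, n_hom_alt):
        if c < 0:
            raise DomainError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise DomainError("at least one genotype required")
    n_a = 2 * n_hom_ref + n_het
    n_b = 2 * n_hom_alt + n_het
    if n_a == 0 or n_b == 0:
        return 1.0, 1.0
    parity = min(n_a, n_b) % 2
    hets, logs = _het_log_probs(parity, n_a, n_b)
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    obs_idx = int(np.nonzero(hets == n_het)[0][0])
    p_obs = probs[obs_idx]
    # relative tolerance guards against ties broken by floating-point noise
    hwe_p = float(probs[probs <= p_obs * (1 + 1e-12)].sum())
    exchet_p = float(probs[hets >= n_het].sum())
    return min(hwe_p, 1.0), min(exchet_p, 1.0)


def compute_site_stats(
    matrix: GenotypeMatrix,
    depths: Optional[np.ndarray] = None,
    quals: Optional[Sequence[Optional[float]]] = None,
) -> list[SiteStats]:
    """Recompute per-site tags from genotype codes.

    ``depths`` is an optional samples x sites array (negative/NaN = absent);
    ``quals`` an optional per-site QUAL sequence.
    """
    if matrix.n_sites == 0 or matrix.n_samples == 0:
        raise DomainError("matrix must be non-empty")
    codes = matrix.codes
    n = matrix.n_samples
    out: list[SiteStats] = []
    for j in range(matrix.n_sites):
        col = codes[:, j]
        n_miss = int((col == -1).sum())
        n_called = n - n_miss
        n_het = int((col == 1).sum())
        n_hom_alt = int((col == 2).sum())
        n_hom_ref = n_called - n_het - n_hom_alt
        call_rate = n_called / n
        if n_called == 0:
            af = 0.0
            frac_het = 0.0
            hwe_p = exchet_p = 1.0
        else:
            af = (n_het + 2 * n_hom_alt) / (2 * n_called)
            frac_het = n_het / n_called
            hwe_p, exchet_p = hwe_exact(n_hom_ref, n_het, n_hom_alt)
        mean_dp = None
        if depths is not None:
            dcol = np.asarray(depths, dtype=float)[:, j]
            valid = np.isfinite(dcol) & (dcol >= 0)
            if valid.any():
                mean_dp = float(dcol[valid].mean())
        qual = None
        if quals is not None:
            qual = quals[j]
        out.append(
            SiteStats(
                call_rate=call_rate,
                f_missing=1.0 - call_rate,
                af=af,
                maf=min(af, 1.0 - af),
                frac_het=frac_het,
                hwe_p=hwe_p,
                exchet_p=exchet_p,
                mean_dp=mean_dp,
                qual=qual,
            )
        )
    return out


# Aliases follow the tag names used by bcftools-style filter expressions.
_TAG_ALIASES = {
    "f_missing": "f_missing",
    "maf": "maf",
    "af": "af",
    "qual": "qual",
    "exchet": "exchet_p",
    "exchet_p": "exchet_p",
    "hwe": "hwe_p",
    "hwe_p": "hwe_p",
    "call_rate": "call_rate",
    "callrate": "call_rate",
    "frac_het": "frac_het",
    "frachet": "frac_het",
    "mean_dp": "mean_dp",
    "dp": "mean_dp",
}

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<lpar>\()|(?P<rpar>\))|(?P<and>&&?)|(?P<or>\|\|?)"
    r"|(?P<op><=|>=|==|<|>)|(?P<num>-?\d+(?:\.\d*)?(?:[eE][+-]?\d+)?)"
    r"|(?P<name>[A-Za-z_][A-Za-z0-9_]*))"
)

_CMP = {
    "<": np.less,
    "<=": np.less_equal,
    ">": np.greater,
    ">=": np.greater_equal,
    "==": np.equal,
}
_FLIP = {"<": ">", "<=": ">=", ">": "<", ">=": "<=", "==": "=="}


class FilterExpression:
    """Boolean site-filter expression over QC tags.

    Grammar (bcftools-style precedence — comparisons bind tighter than the
    logical connectives): comparisons ``TAG op NUMBER`` with ``<``, ``<=``,
    ``>``, ``>=``, ``==``, combined with ``&``, ``|`` and parentheses, enough
    for ``(F_MISSING<0.5 & MAF>0.2 & QUAL>100000 & (ExcHet>0.5 | HWE>0.5))``.
    Unknown tag names are rejected at parse time.  A comparison on a tag that
    is absent for a site (e.g. missing QUAL) is false.
    """

    def __init__(self, text: str):
        self.text = text
        self._tokens = self._tokenize(text)
        self._pos = 0
        self._root = self._parse_or()
        if self._pos != len(self._tokens):
            raise FilterParseError(
                f"unexpected token {self._tokens[self._pos][1]!r} in {text!r}"
            )

    def _tokenize(self, text: str) -> list[tuple[str, str]]:
        tokens = []
        pos = 0
        while pos < len(text):
            m = _TOKEN_RE.match(text, pos)
            if m is None or m.end() == pos:
                raise FilterParseError(f"cannot tokenize {text!r} at offset {pos}")
            kind = m.lastgroup
            tokens.append((kind, m.group(kind)))
            pos = m.end()
        return tokens

    def _peek(self) -> Optional[tuple[str, str]]:
        return self._tokens[self._pos] if self._pos < len(self._tokens) else None

    def _next(self) -> tuple[str, str]:
        tok = self._peek()
        if tok is None:
            raise FilterParseError(f"unexpected end of filter {self.text!r}")
        self._pos += 1
        return tok

    def _parse_or(self):
        node = self._parse_and()
        while self._peek() and self._peek()[0] == "or":
            self._next()
            node = ("or", node, self._parse_and())
        return node

    def _parse_and(self):
        node = self._parse_atom()
        while self._peek() and self._peek()[0] == "and":
            self._next()
            node = ("and", node, self._parse_atom())
        return node

    def _parse_atom(self):
        tok = self._next()
        if tok[0] == "lpar":
            node = self._parse_or()
            closing = self._next()
            if closing[0] != "rpar":
                raise FilterParseError(f"missing ')' in {self.text!r}")
            return node
        if tok[0] == "name":
            op = self._next()
            num = self._next()
            if op[0] != "op" or num[0] != "num":
                raise FilterParseError(f"malformed comparison in {self.text!r}")
            return self._cmp_node(tok[1], op[1], num[1])
        if tok[0] == "num":
            op = self._next()
            name = self._next()
            if op[0] != "op" or name[0] != "name":
                raise FilterParseError(f"malformed comparison in {self.text!r}")
            return self._cmp_node(name[1], _FLIP[op[1]], tok[1])
        raise FilterParseError(f"unexpected token {tok[1]!r} in {self.text!r}")

    def _cmp_node(self, name: str, op: str, num: str):
        if name.lower() not in _TAG_ALIASES:
            raise FilterParseError(f"unknown tag {name!r} in {self.text!r}")
        return ("cmp", _TAG_ALIASES[name.lower()], op, float(num))

    def tags(self) -> set[str]:
        out: set[str] = set()

        def walk(node) -> None:
            if node[0] == "cmp":
                out.add(node[1])
            else:
                walk(node[1])
                walk(node[2])

        walk(self._root)
        return out

    def evaluate(self, columns: dict[str, np.ndarray]) -> np.ndarray:
        return self._eval(self._root, columns)

    def _eval(self, node, cols: dict[str, np.ndarray]) -> np.ndarray:
        kind = node[0]
        if kind == "and":
            return self._eval(node[1], cols) & self._eval(node[2], cols)
        if kind == "or":
            return self._eval(node[1], cols) | self._eval(node[2], cols)
        _, tag, op, value = node
        values = cols[tag]
        with np.errstate(invalid="ignore"):
            mask = _CMP[op](values, value)
        return mask & ~np.isnan(values)


def _stats_columns(stats: Sequence[SiteStats]) -> dict[str, np.ndarray]:
    def col(attr: str) -> np.ndarray:
        return np.array(
            [getattr(s, attr) if getattr(s, attr) is not None else np.nan for s in stats],
            dtype=float,
        )

    return {
        name: col(name)
        for name in (
            "call_rate",
            "f_missing",
            "af",
            "maf",
            "frac_het",
            "hwe_p",
            "exchet_p",
            "mean_dp",
            "qual",
        )
    }


def eval_filter(
    stats: Sequence[SiteStats], expr: "FilterExpression | str"
) -> np.ndarray:
    """Boolean mask of sites satisfying a filter expression."""
    if isinstance(expr, str):
        expr = FilterExpression(expr)
    return expr.evaluate(_stats_columns(stats))


def _pairwise_complete_r2(a: np.ndarray, b: np.ndarray) -> Optional[float]:
    mask = (a >= 0) & (b >= 0)
    if mask.sum() < 2:
        return None
    x = a[mask].astype(float)
    y = b[mask].astype(float)
    sx = x.std()
    sy = y.std()
    if sx == 0.0 or sy == 0.0:
        return None
    r = float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))
    return r * r


def ld_prune(
    matrix: GenotypeMatrix, r2_max: float = 0.8, window_bp: int = 100_000
) -> list[int]:
    """Greedy left-to-right LD pruning on genotype-code r^2.

    A site is removed when its squared Pearson correlation (composite LD over
    pairwise-complete samples) with any *retained* site within ``window_bp``
    upstream on the same chromosome exceeds ``r2_max``.  Zero-variance sites
    are retained and never trigger removals.  Returns retained indices,
    sorted.
    """
    if not 0.0 <= r2_max <= 1.0:
        raise DomainError(f"r2_max must be in [0, 1], got {r2_max}")
    retained: list[int] = []
    # retained comparators per chromosome: (pos, column, has_variance)
    active: dict[str, list[tuple[int, np.ndarray, bool]]] = {}
    for j, site in enumerate(matrix.sites):
        col = matrix.codes[:, j]
        called = col[col >= 0]
        has_var = called.size >= 2 and called.std() > 0
        drop = False
        if has_var:
            for pos, other, other_var in active.get(site.chrom, []):
                if site.pos - pos > window_bp or not other_var:
                    continue
                r2 = _pairwise_complete_r2(col, other)
                if r2 is not None and r2 > r2_max:
                    drop = True
                    break
        if not drop:
            retained.append(j)
            active.setdefault(site.chrom, []).append((site.pos, col, has_var))
            # window is bounded, so old comparators can be discarded
            active[site.chrom] = [
                t for t in active[site.chrom] if site.pos - t[0] <= window_bp
            ]
    return retained


def cumulative_filter_curve(
    values: Iterable[float],
    direction: str = "max_relaxed",
    bin_edges: Optional[Sequence[float]] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram plus survivor counts per threshold for QC filter curves.

    ``max_relaxed``: the relaxed end is the minimum edge (no filter); the
    cumulative count at edge ``t`` is the number of values >= t.
    ``min_relaxed`` is the mirror (count of values <= t).  Both are monotone
    from the total at the relaxed end toward 0.
    """
    vals = np.asarray(list(values), dtype=float)
    if direction not in ("max_relaxed", "min_relaxed"):
        raise DomainError(f"unknown direction {direction!r}")
    if bin_edges is None:
        bin_edges = np.linspace(vals.min(), vals.max(), 21) if vals.size else [0, 1]
    edges = np.asarray(bin_edges, dtype=float)
    if not np.all(np.diff(edges) > 0):
        raise DomainError("bin_edges must be strictly increasing")
    if vals.size == 0:
        return np.zeros(len(edges) - 1, dtype=int), np.zeros(len(edges), dtype=int)
    hist, _ = np.histogram(vals, bins=edges)
    if direction == "max_relaxed":
        cumulative = np.array([(vals >= t).sum() for t in edges])
    else:
        cumulative = np.array([(vals <= t).sum() for t in edges])
    return hist, cumulative


def genotype_vs_allele_freq(
    matrix: GenotypeMatrix,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Observed genotype frequencies vs alternate allele frequency per site.

    Returns an array with columns (p, f_homref, f_het, f_homalt) over sites
    with at least one non-missing genotype, plus the random-mating
    expectations q^2, 2pq, p^2 evaluated at each site's p.
    """
    rows = []
    for j in range(matrix.n_sites):
        col = matrix.codes[:, j]
        called = col[col >= 0]
        m = called.size
        if m == 0:
            continue
        n_het = int((called == 1).sum())
        n_alt = int((called == 2).sum())
        p = (n_het + 2 * n_alt) / (2 * m)
        rows.append((p, (m - n_het - n_alt) / m, n_het / m, n_alt / m))
    obs = np.asarray(rows, dtype=float).reshape(-1, 4)
    p = obs[:, 0]
    q = 1.0 - p
    expected = {"f_homref": q * q, "f_het": 2 * p * q, "f_homalt": p * p}
    return obs, expected


def neg_log10(p: "np.ndarray | float") -> np.ndarray:
    """-log10 transform with p clipped at 1e-30 for finite plot values."""
    return -np.log10(np.clip(p, P_CLIP, None))


def stats_table(matrix: GenotypeMatrix, stats: Sequence[SiteStats], path) -> None:
    """Write a tab-delimited per-site stats table (one column per tag)."""
    import pandas as pd

    df = pd.DataFrame(
        {
            "chrom": [s.chrom for s in matrix.sites],
            "pos": [s.pos for s in matrix.sites],
            "ref": [s.ref for s in matrix.sites],
            "alt": [",".join(s.alts) for s in matrix.sites],
            "call_rate": [s.call_rate for s in stats],
            "f_missing": [s.f_missing for s in stats],
            "af": [s.af for s in stats],
            "maf": [s.maf for s in stats],
            "frac_het": [s.frac_het for s in stats],
            "hwe_p": [s.hwe_p for s in stats],
            "exchet_p": [s.exchet_p for s in stats],
            "mean_dp": [s.mean_dp for s in stats],
            "qual": [s.qual for s in stats],
        }
    )
    df.to_csv(path, sep="\t", index=False)
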