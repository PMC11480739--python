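"""Genetic distances, clustering, neighbor joining, Newick and classical MDS.

Two genotype-code distances are provided for diploid 0/1/2 codes:

* ``hamming_fraction`` — fraction of jointly non-missing sites at which the
  codes differ (the haplotype-viewer clustering distance);
* ``one_minus_ibs`` — 1 minus the fraction of shared alleles, where a site
  contributes ``2 - |codeA - codeB|`` shared alleles out of 2 (plink-style
  1-IBS distance).

Hierarchical clustering (average or complete linkage) yields an ultrametric
tree, a deterministic leaf order and an exact K-cluster cut of the merge
sequence.  Neighbor joining (Saitou-Nei) builds the unrooted tree used for
genome-wide phylogenies.  Classical (Torgerson) MDS double-centers the squared
distance matrix and eigendecomposes it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage as _scipy_linkage
from scipy.spatial.distance import squareform

from .errors import DomainError
from .vcf_model import GenotypeMatrix

__all__ = [
    "DistanceMatrix",
    "TreeNode",
    "Partition",
    "MDSResult",
    "pairwise_distance",
    "hier_cluster",
    "neighbor_joining",
    "heatmap_layout",
    "render_heatmap",
    "classical_mds",
    "HEATMAP_COLORS",
]

#: fixed haplotype-viewer color coding of genotype codes
HEATMAP_COLORS = {0: "gray", 1: "yellow", 2: "red", -1: "white"}


@dataclass
class DistanceMatrix:
    """Labelled symmetric distance matrix with zero diagonal, values in [0, 1]."""

    labels: list[str]
    d: np.ndarray = field(repr=False)
    metric: str = "hamming_fraction"

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise DomainError(f"distance matrix shape {self.d.shape} != ({n}, {n})")
        if not np.allclose(self.d, self.d.T):
            raise DomainError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise DomainError("distance matrix diagonal must be zero")

    @property
    def n(self) -> int:
        return len(self.labels)


@dataclass
class TreeNode:
    """Node of a (possibly unrooted) tree with branch lengths."""

    name: Optional[str] = None
    length: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf():
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.leaves()]

    def to_newick(self, with_lengths: bool = True) -> str:
        return self._newick(with_lengths) + ";"

    def _newick(self, with_lengths: bool) -> str:
        if self.is_leaf():
            body = _quote_label(self.name or "")
        else:
            body = "(" + ",".join(c._newick(with_lengths) for c in self.children) + ")"
            if self.name:
                body += _quote_label(self.name)
        if with_lengths:
            body += f":{self.length:g}"
        return body


def _quote_label(label: str) -> str:
    if any(c in label for c in " ():;,'[]"):
        return "'" + label.replace("'", "''") + "'"
    return label


@dataclass(frozen=True)
class Partition:
    """Assignment of every sample to exactly one cluster id in 1..K."""

    assignment: dict[str, int]

    def __post_init__(self) -> None:
        ids = sorted(set(self.assignment.values()))
        if not ids:
            raise DomainError("empty partition")
        if ids != list(range(1, len(ids) + 1)):
            raise DomainError(f"cluster ids must be 1..K without gaps, got {ids}")

    @property
    def k(self) -> int:
        return len(set(self.assignment.values()))

    def members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for name, cid in self.assignment.items():
            out.setdefault(cid, []).append(name)
        return out

    @classmethod
    def from_labels(cls, labels: dict[str, object]) -> "Partition":
        """Build a partition from arbitrary labels, ids assigned by sort order."""
        uniq = sorted({str(v) for v in labels.values()})
        mapping = {v: i + 1 for i, v in enumerate(uniq)}
        return cls({k: mapping[str(v)] for k, v in labels.items()})


@dataclass
class MDSResult:
    """Classical-MDS coordinates (samples x components) and eigenvalues."""

    labels: list[str]
    coordinates: np.ndarray
    eigenvalues: np.ndarray


def pairwise_distance(
    matrix: GenotypeMatrix, metric: str = "one_minus_ibs"
) -> DistanceMatrix:
    """Pairwise sample distances over jointly non-missing sites.

    Pairs with no jointly called site get distance 1 with a warning.
    """
    if metric not in ("hamming_fraction", "one_minus_ibs"):
        raise DomainError(f"unknown metric {metric!r}")
    n = matrix.n_samples
    if n < 2:
        raise DomainError("need at least 2 samples")
    codes = matrix.codes.astype(np.int16)
    d = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = codes[i], codes[j]
            mask = (a >= 0) & (b >= 0)
            m = int(mask.sum())
            if m == 0:
                warnings.warn(
                    f"samples {matrix.samples[i]!r} and {matrix.samples[j]!r} share "
                    "no called sites; distance set to 1",
                    stacklevel=2,
                )
                dist = 1.0
            elif metric == "hamming_fraction":
                dist = float((a[mask] != b[mask]).mean())
            else:
                shared = (2 - np.abs(a[mask] - b[mask])).sum()
                dist = 1.0 - shared / (2.0 * m)
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(list(matrix.samples), d, metric)


def _linkage_tree(Z: np.ndarray, labels: Sequence[str]) -> tuple[TreeNode, list[int]]:
    """Build an ultrametric TreeNode from a scipy linkage matrix.

    At every internal node the child whose subtree holds the smaller minimum
    original index comes first; the returned list is the induced leaf order.
    """
    n = len(labels)
    nodes: dict[int, TreeNode] = {
        i: TreeNode(name=labels[i]) for i in range(n)
    }
    height = {i: 0.0 for i in range(n)}
    min_idx = {i: i for i in range(n)}
    for r, (a, b, h, _cnt) in enumerate(Z):
        a, b = int(a), int(b)
        if min_idx[b] < min_idx[a]:
            a, b = b, a
        for child in (a, b):
            nodes[child].length = float(h) - height[child]
        parent = TreeNode(children=[nodes[a], nodes[b]])
        nodes[n + r] = parent
        height[n + r] = float(h)
        min_idx[n + r] = min(min_idx[a], min_idx[b])
    root = nodes[n + len(Z) - 1] if len(Z) else nodes[0]
    label_pos = {lab: i for i, lab in enumerate(labels)}
    order = [label_pos[name] for name in root.leaf_names()]
    return root, order


def hier_cluster(
    d: DistanceMatrix,
    linkage: str = "average",
    k: Optional[int] = None,
) -> tuple[TreeNode, list[int], Optional[Partition]]:
    """Agglomerative clustering: ultrametric tree, leaf order, optional K-cut.

    The K-cut undoes the last ``k - 1`` merges of the merge sequence so that
    exactly ``k`` clusters always result; cluster ids are assigned by each
    cluster's smallest original sample index.
    """
    if linkage not in ("average", "complete"):
        raise DomainError(f"unsupported linkage {linkage!r}")
    n = d.n
    if k is not None and not 1 <= k <= n:
        raise DomainError(f"k must be in 1..{n}, got {k}")
    condensed = squareform(d.d, checks=False)
    Z = _scipy_linkage(condensed, method=linkage)
    tree, order = _linkage_tree(Z, d.labels)
    partition = None
    if k is not None:
        # replay the first n - k merges of the merge sequence: exactly k groups
        groups: dict[int, set[int]] = {i: {i} for i in range(n)}
        for r, row in enumerate(Z[: n - k]):
            a, b = int(row[0]), int(row[1])
            groups[n + r] = groups.pop(a) | groups.pop(b)
        clusters = sorted(groups.values(), key=min)
        assignment: dict[str, int] = {}
        for cid, members in enumerate(clusters, start=1):
            for i in members:
                assignment[d.labels[i]] = cid
        partition = Partition(assignment)
    return tree, order, partition


def neighbor_joining(d: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining; returns an unrooted tree (trifurcating root).

    Ties in the Q matrix break toward the smallest (i, j) index pair; negative
    branch lengths are clamped to zero with the deficit moved to the sibling
    branch.
    """
    n = d.n
    if n < 3:
        raise DomainError("neighbor joining needs at least 3 labels")
    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in d.labels]
    dist = d.d.astype(float).copy()
    while len(nodes) > 3:
        r = len(nodes)
        row_sums = dist.sum(axis=1)
        q = (r - 2) * dist - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(q, np.inf)
        iu = np.triu_indices(r, k=1)
        flat = q[iu]
        best = int(np.argmin(flat))  # first occurrence = smallest (i, j)
        i, j = int(iu[0][best]), int(iu[1][best])
        dij = dist[i, j]
        bi = 0.5 * dij + (row_sums[i] - row_sums[j]) / (2.0 * (r - 2))
        bj = dij - bi
        if bi < 0:
            bi, bj = 0.0, dij
        elif bj < 0:
            bj, bi = 0.0, dij
        nodes[i].length = bi
        nodes[j].length = bj
        parent = TreeNode(children=[nodes[i], nodes[j]])
        new_d = 0.5 * (dist[i, :] + dist[j, :] - dij)
        keep = [x for x in range(r) if x not in (i, j)]
        dist = np.vstack(
            [
                np.hstack([dist[np.ix_(keep, keep)], new_d[keep, None]]),
                np.hstack([new_d[keep], [0.0]]),
            ]
        )
        nodes = [nodes[x] for x in keep] + [parent]
    # connect the last three nodes to a central (unrooted) vertex
    d01, d02, d12 = dist[0, 1], dist[0, 2], dist[1, 2]
    lengths = [
        0.5 * (d01 + d02 - d12),
        0.5 * (d01 + d12 - d02),
        0.5 * (d02 + d12 - d01),
    ]
    for node, ln in zip(nodes, lengths):
        node.length = max(ln, 0.0)
    return TreeNode(children=list(nodes))


@dataclass
class HeatmapLayout:
    """Row-ordered genotype codes plus the fixed color legend."""

    row_labels: list[str]
    codes: np.ndarray
    color_map: dict[int, str]
    label_colors: Optional[dict[str, str]] = None
    row_label_values: Optional[list[object]] = None


_LABEL_PALETTE = ["blue", "red", "green", "orange", "purple", "brown", "cyan"]


def heatmap_layout(
    matrix: GenotypeMatrix,
    leaf_order: Sequence[int],
    labels: Optional[dict[str, object]] = None,
) -> HeatmapLayout:
    """Permute matrix rows to a clustering leaf order for heatmap display.

    Colors are fixed: 0 gray, 1 yellow, 2 red, -1 white; when per-sample
    labels are given a label color column is appended, one color per distinct
    label in sorted order.
    """
    order = list(leaf_order)
    if sorted(order) != list(range(matrix.n_samples)):
        raise DomainError("leaf_order must be a permutation of sample indices")
    row_labels = [matrix.samples[i] for i in order]
    codes = matrix.codes[order, :]
    label_colors = None
    values = None
    if labels is not None:
        uniq = sorted({str(labels[s]) for s in matrix.samples if s in labels})
        palette = {
            lab: _LABEL_PALETTE[i % len(_LABEL_PALETTE)] for i, lab in enumerate(uniq)
        }
        label_colors = {
            s: palette[str(labels[s])] for s in matrix.samples if s in labels
        }
        values = [labels.get(s) for s in row_labels]
    return HeatmapLayout(row_labels, codes, dict(HEATMAP_COLORS), label_colors, values)


def render_heatmap(layout: HeatmapLayout, path: str) -> None:
    """Render a heatmap layout to SVG/PNG with matplotlib."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    code_to_idx = {-1: 0, 0: 1, 1: 2, 2: 3}
    cmap = ListedColormap(["white", "gray", "yellow", "red"])
    img = np.vectorize(code_to_idx.get)(layout.codes)
    fig, ax = plt.subplots(
        figsize=(max(4, layout.codes.shape[1] * 0.12), max(3, len(layout.row_labels) * 0.25))
    )
    ax.imshow(img, cmap=cmap, vmin=0, vmax=3, aspect="auto", interpolation="nearest")
    ax.set_yticks(range(len(layout.row_labels)))
    ax.set_yticklabels(layout.row_labels, fontsize=6)
    ax.set_xticks([])
    if layout.label_colors:
        for y, name in enumerate(layout.row_labels):
            color = layout.label_colors.get(name)
            if color:
                ax.plot(
                    layout.codes.shape[1] - 0.2, y, "s", color=color, markersize=4
                )
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def classical_mds(d: DistanceMatrix, n_components: int = 5) -> MDSResult:
    """Classical (Torgerson) MDS of a distance matrix.

    Double-centers -0.5 * J D^2 J, eigendecomposes, and keeps the top
    ``n_components`` non-negative eigenvalues; coordinates are eigenvectors
    scaled by sqrt(eigenvalue).  Each coordinate column is sign-fixed so its
    largest-magnitude entry is positive.  Components with negative eigenvalue
    are truncated to zero with a warning.
    """
    if n_components < 1:
        raise DomainError("n_components must be >= 1")
    n = d.n
    if n_components > n - 1:
        raise DomainError(f"n_components must be <= n - 1 = {n - 1}")
    d2 = d.d**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1][:n_components]
    vals = eigvals[order]
    vecs = eigvecs[:, order]
    coords = np.zeros((n, n_components))
    out_vals = np.maximum(vals, 0.0)
    if np.any(vals < -1e-9 * max(abs(eigvals).max(), 1.0)):
        warnings.warn(
            "distance matrix is not Euclidean-embeddable in the requested "
            "dimension; negative eigenvalues truncated to zero",
            stacklevel=2,
        )
    pos = out_vals > 0
    coords[:, pos] = vecs[:, pos] * np.sqrt(out_vals[pos])
    for c in range(n_components):
        col = coords[:, c]
        if col.any():
            top = np.argmax(np.abs(col))
            if col[top] < 0:
                coords[:, c] = -col
    return MDSResult(list(d.labels), coords, out_vals)
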