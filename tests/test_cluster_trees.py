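"""Distances, hierarchical clustering, neighbor joining, MDS, heatmap layout."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_additive_tree, rf_distance
from snpdesk.cluster_trees import (
    DistanceMatrix,
    classical_mds,
    heatmap_layout,
    hier_cluster,
    neighbor_joining,
    pairwise_distance,
)
from snpdesk.errors import DomainError
from snpdesk.vcf_model import GenotypeMatrix, SiteEntry


def row_matrix(rows, samples=None):
    rows = np.array(rows, dtype=np.int8)
    samples = samples or [f"s{i}" for i in range(rows.shape[0])]
    sites = [SiteEntry("chr1", 100 * (j + 1), "A", ("G",)) for j in range(rows.shape[1])]
    return GenotypeMatrix(samples, sites, rows)


class TestPairwiseDistance:
    def test_identical_rows_are_zero(self):
        m = row_matrix([[0, 1, 2], [0, 1, 2]])
        for metric in ("hamming_fraction", "one_minus_ibs"):
            assert pairwise_distance(m, metric).d[0, 1] == 0.0

    def test_opposite_homozygotes_are_one(self):
        m = row_matrix([[0, 0, 0], [2, 2, 2]])
        assert pairwise_distance(m, "hamming_fraction").d[0, 1] == 1.0
        assert pairwise_distance(m, "one_minus_ibs").d[0, 1] == 1.0

    def test_shared_allele_counting(self):
        m = row_matrix([[0, 1, 2], [0, 2, 2]])
        assert pairwise_distance(m, "hamming_fraction").d[0, 1] == pytest.approx(1 / 3)
        # shared alleles per site: 2, 1, 2 of 6
        assert pairwise_distance(m, "one_minus_ibs").d[0, 1] == pytest.approx(1 / 6)

    def test_missing_sites_excluded(self):
        m = row_matrix([[0, -1, 2], [0, 1, -1]])
        assert pairwise_distance(m, "hamming_fraction").d[0, 1] == 0.0

    def test_no_overlap_pair_warns_distance_one(self):
        m = row_matrix([[0, -1], [-1, 1]])
        with pytest.warns(UserWarning, match="no called sites"):
            d = pairwise_distance(m, "one_minus_ibs")
        assert d.d[0, 1] == 1.0

    def test_single_sample_rejected(self):
        m = row_matrix([[0, 1]])
        with pytest.raises(DomainError):
            pairwise_distance(m)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_hamming_dominates_one_minus_ibs_and_triangle(self, seed):
        rng = np.random.default_rng(seed)
        m = row_matrix(rng.integers(0, 3, size=(5, 12)))
        dh = pairwise_distance(m, "hamming_fraction").d
        di = pairwise_distance(m, "one_minus_ibs").d
        assert np.all(dh >= di - 1e-12)
        for metric_d in (dh, di):
            for i in range(5):
                for j in range(5):
                    for k in range(5):
                        assert metric_d[i, j] <= metric_d[i, k] + metric_d[k, j] + 1e-12
            assert np.allclose(metric_d, metric_d.T)


class TestHierCluster:
    def test_two_tight_pairs_cut_into_pairs(self):
        d = np.array(
            [
                [0.0, 0.05, 0.9, 0.9],
                [0.05, 0.0, 0.9, 0.9],
                [0.9, 0.9, 0.0, 0.05],
                [0.9, 0.9, 0.05, 0.0],
            ]
        )
        dm = DistanceMatrix(["a", "b", "c", "d"], d)
        _, _, part = hier_cluster(dm, "average", k=2)
        assert part.assignment == {"a": 1, "b": 1, "c": 2, "d": 2}

    def test_equal_distances_still_yield_exact_k(self):
        n = 5
        d = np.ones((n, n)) - np.eye(n)
        dm = DistanceMatrix([f"s{i}" for i in range(n)], d)
        _, _, part = hier_cluster(dm, "average", k=2)
        assert part.k == 2

    def test_three_point_agglomeration_order(self):
        d = np.array([[0.0, 0.1, 0.9], [0.1, 0.0, 0.9], [0.9, 0.9, 0.0]])
        dm = DistanceMatrix(["A", "B", "C"], d)
        tree, order, _ = hier_cluster(dm, "average")
        # first merge (A, B) at 0.1, then C joins at 0.9
        assert tree.to_newick(with_lengths=False) == "((A,B),C);"
        assert order == [0, 1, 2]

    def test_leaf_order_prefers_smaller_min_index_subtree(self):
        d = np.array(
            [
                [0.0, 0.9, 0.9, 0.1],
                [0.9, 0.0, 0.1, 0.9],
                [0.9, 0.1, 0.0, 0.9],
                [0.1, 0.9, 0.9, 0.0],
            ]
        )
        dm = DistanceMatrix(["a", "b", "c", "d"], d)
        _, order, _ = hier_cluster(dm, "average")
        assert order == [0, 3, 1, 2]  # subtree containing index 0 first

    def test_k_larger_than_n_rejected(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0.0, 0.5], [0.5, 0.0]]))
        with pytest.raises(DomainError):
            hier_cluster(dm, "average", k=3)

    def test_ultrametric_heights_nonnegative_branches(self):
        rng = np.random.default_rng(8)
        x = rng.random((6, 4))
        d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
        d /= d.max()
        dm = DistanceMatrix([f"s{i}" for i in range(6)], d)
        tree, _, _ = hier_cluster(dm, "complete")

        def walk(node):
            assert node.length >= -1e-12
            for c in node.children:
                walk(c)

        walk(tree)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(
            ["A", "B", "C"], np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float)
        )
        tree = neighbor_joining(dm)
        lengths = {leaf.name: leaf.length for leaf in tree.leaves()}
        assert lengths == pytest.approx({"A": 1.0, "B": 1.0, "C": 3.0})

    def test_additive_four_taxon_metric_recovered_exactly(self):
        # tree ((A:1,B:2):1,(C:3,D:1):0) -> additive distances
        d = np.array(
            [
                [0, 3, 5, 3],
                [3, 0, 6, 4],
                [5, 6, 0, 4],
                [3, 4, 4, 0],
            ],
            dtype=float,
        )
        dm = DistanceMatrix(["A", "B", "C", "D"], d)
        tree = neighbor_joining(dm)
        # recovered tree must reproduce all pairwise path lengths
        assert _tree_distances(tree) == pytest.approx(
            {frozenset(p): v for p, v in {
                ("A", "B"): 3, ("A", "C"): 5, ("A", "D"): 3,
                ("B", "C"): 6, ("B", "D"): 4, ("C", "D"): 4,
            }.items()}
        )

    def test_zero_matrix_star_tree(self):
        dm = DistanceMatrix(["A", "B", "C"], np.zeros((3, 3)))
        tree = neighbor_joining(dm)
        assert all(leaf.length == 0.0 for leaf in tree.leaves())

    def test_fewer_than_three_rejected(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(DomainError):
            neighbor_joining(dm)

    @pytest.mark.parametrize("n_leaves", [5, 8, 12])
    def test_recovers_random_additive_topology(self, n_leaves):
        rng = np.random.default_rng(100 + n_leaves)
        for _ in range(3):
            true_newick, labels, d = random_additive_tree(rng, n_leaves)
            tree = neighbor_joining(DistanceMatrix(labels, d / max(d.max(), 1.0)))
            assert rf_distance(true_newick, tree.to_newick()) == 0

    def test_matches_skbio_reference_topology(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(77)
        _, labels, d = random_additive_tree(rng, 7)
        d = d / d.max()
        ours = neighbor_joining(DistanceMatrix(labels, d))
        ref = skbio.tree.nj(skbio.DistanceMatrix(d, ids=labels))
        assert rf_distance(ours.to_newick(), str(ref).strip()) == 0


def _tree_distances(tree):
    """Leaf-to-leaf path lengths of a TreeNode tree (test-side traversal)."""
    dists = {}

    def depths(node, acc):
        if node.is_leaf():
            return {node.name: acc + node.length}
        out = {}
        for c in node.children:
            out.update(depths(c, acc + node.length))
        return out

    def visit(node):
        if node.is_leaf():
            return
        child_maps = [depths(c, 0.0) for c in node.children]
        for i in range(len(child_maps)):
            for j in range(i + 1, len(child_maps)):
                for a, da in child_maps[i].items():
                    for b, db in child_maps[j].items():
                        dists[frozenset((a, b))] = da + db
        for c in node.children:
            visit(c)

    visit(tree)
    return dists


class TestHeatmapLayout:
    def test_identity_and_reversed_orders(self, toy_matrix):
        n = toy_matrix.n_samples
        same = heatmap_layout(toy_matrix, list(range(n)))
        assert np.array_equal(same.codes, toy_matrix.codes)
        rev = heatmap_layout(toy_matrix, list(range(n))[::-1])
        assert np.array_equal(rev.codes, toy_matrix.codes[::-1])
        assert rev.row_labels == toy_matrix.samples[::-1]

    def test_fixed_color_coding(self, toy_matrix):
        layout = heatmap_layout(toy_matrix, [0, 1, 2])
        assert layout.color_map == {0: "gray", 1: "yellow", 2: "red", -1: "white"}

    def test_labels_append_color_column(self, toy_matrix):
        labels = {"X": "hemp", "Y": "drug", "Z": "hemp"}
        layout = heatmap_layout(toy_matrix, [2, 1, 0], labels)
        assert layout.row_label_values == ["hemp", "drug", "hemp"]
        assert layout.label_colors["X"] == layout.label_colors["Z"]
        assert layout.label_colors["X"] != layout.label_colors["Y"]

    def test_non_permutation_rejected(self, toy_matrix):
        with pytest.raises(DomainError):
            heatmap_layout(toy_matrix, [0, 0, 1])


class TestClassicalMds:
    def test_collinear_points_one_component(self):
        d = np.array([[0, 1, 3], [1, 0, 2], [3, 2, 0]], dtype=float)
        dm = DistanceMatrix(["a", "b", "c"], d)
        res = classical_mds(dm, 2)
        x = res.coordinates[:, 0]
        for i in range(3):
            for j in range(3):
                assert abs(x[i] - x[j]) == pytest.approx(d[i, j], abs=1e-9)
        assert res.eigenvalues[1] == pytest.approx(0.0, abs=1e-9)

    def test_recovers_planar_configuration(self):
        rng = np.random.default_rng(4)
        pts = rng.random((7, 2))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        dm = DistanceMatrix([f"s{i}" for i in range(7)], d)
        res = classical_mds(dm, 6)
        rec = np.sqrt(
            ((res.coordinates[:, None] - res.coordinates[None, :]) ** 2).sum(-1)
        )
        assert np.allclose(rec, d, atol=1e-9)

    def test_regular_simplex_equal_eigenvalues(self):
        d = np.ones((4, 4)) - np.eye(4)
        dm = DistanceMatrix(list("abcd"), d)
        res = classical_mds(dm, 3)
        assert res.eigenvalues == pytest.approx([0.5] * 3)

    def test_column_means_centred_and_sign_convention(self):
        rng = np.random.default_rng(12)
        pts = rng.random((6, 3))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        res = classical_mds(DistanceMatrix([f"s{i}" for i in range(6)], d), 3)
        assert np.allclose(res.coordinates.mean(axis=0), 0.0, atol=1e-9)
        for c in range(3):
            col = res.coordinates[:, c]
            assert col[np.argmax(np.abs(col))] >= 0

    def test_component_bounds(self):
        dm = DistanceMatrix(["a", "b", "c"], np.ones((3, 3)) - np.eye(3))
        with pytest.raises(DomainError):
            classical_mds(dm, 0)
        with pytest.raises(DomainError):
            classical_mds(dm, 3)


def test_newick_round_trips_through_dendropy(toy_matrix):
    import dendropy

    d = pairwise_distance(toy_matrix, "one_minus_ibs")
    tree, _, _ = hier_cluster(d, "average")
    parsed = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
    assert sorted(l.taxon.label for l in parsed.leaf_node_iter()) == sorted(
        toy_matrix.samples
    )
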