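"""Ordering and display geometry: Ward clustering, polar layout,
similarity network and cluster extraction."""

import numpy as np
import pytest

from zfscreen.chem import SimilarityMatrix, similarity_matrix
from zfscreen.layout import (
    build_network,
    extract_clusters,
    order_heatmap,
    polar_layout,
    ward_cluster,
)
from zfscreen.triage import Category, TriageRecord

from conftest import compound


def matrix(values, ids=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"c{i}" for i in range(len(values))]
    return SimilarityMatrix(ids, values)


def ward_oracle(dist):
    """O(n^3) Lance-Williams Ward agglomeration.

    Returns the cophenetic matrix (height at which each pair first joins)
    -- a label-order-independent summary of the merge sequence.
    """
    n = len(dist)
    d = {(i, j): float(dist[i][j]) for i in range(n) for j in range(n) if i < j}
    clusters = {i: [i] for i in range(n)}
    coph = np.zeros((n, n))
    while len(clusters) > 1:
        (i, j), dij = min(d.items(), key=lambda kv: kv[1])
        for a in clusters[i]:
            for b in clusters[j]:
                coph[a, b] = coph[b, a] = dij
        ni, nj = len(clusters[i]), len(clusters[j])
        merged = clusters.pop(i) + clusters.pop(j)
        new = {}
        for (a, b), dab in d.items():
            if i in (a, b) and j in (a, b):
                continue
            if i in (a, b) or j in (a, b):
                continue
            new[(a, b)] = dab
        for k in clusters:
            nk = len(clusters[k])
            dki = d[tuple(sorted((k, i)))]
            dkj = d[tuple(sorted((k, j)))]
            # Lance-Williams update for Ward's criterion
            new[tuple(sorted((k, i)))] = np.sqrt(
                ((ni + nk) * dki**2 + (nj + nk) * dkj**2 - nk * dij**2)
                / (ni + nj + nk)
            )
        clusters[i] = merged
        d = new
    return coph


class TestWardCluster:
    def test_identical_pair_merges_at_zero(self):
        m = matrix([[1.0, 1.0], [1.0, 1.0]])
        order = ward_cluster(m)
        assert order.linkage[0, 2] == pytest.approx(0.0)

    def test_singleton(self):
        order = ward_cluster(matrix([[1.0]]))
        assert order.linkage.shape == (0, 4)
        assert list(order.leaf_order) == [0]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ward_cluster(matrix(np.empty((0, 0))))

    def test_matches_lance_williams_oracle(self):
        # hand-set 4-point similarity matrix with distinct distances
        s = np.array(
            [
                [1.0, 0.9, 0.2, 0.1],
                [0.9, 1.0, 0.3, 0.15],
                [0.2, 0.3, 1.0, 0.7],
                [0.1, 0.15, 0.7, 1.0],
            ]
        )
        from scipy.cluster.hierarchy import cophenet
        from scipy.spatial.distance import squareform

        order = ward_cluster(matrix(s))
        got = squareform(cophenet(order.linkage))
        expected = ward_oracle(1.0 - s)
        assert np.allclose(got, expected)

    def test_heights_monotone_on_fingerprint_data(self, small_library):
        m = similarity_matrix(small_library[0][:40])
        order = ward_cluster(m)
        heights = order.linkage[:, 2]
        assert np.all(np.diff(heights) >= -1e-9)
        assert sorted(order.leaf_order) == list(range(40))


class TestPolarLayout:
    def test_quarter_angles_without_jitter(self):
        m = matrix(np.eye(4) * 0 + np.eye(4))
        order = ward_cluster(matrix(np.eye(4)))
        ids = [f"c{i}" for i in range(4)]
        cats = [Category.A] * 4
        pl = polar_layout(order, ids, cats, jitter=False)
        expected = {0.0, np.pi / 2, np.pi, 3 * np.pi / 2}
        assert set(np.round(pl.angle, 10)) == set(np.round(list(expected), 10))

    def test_deterministic_under_seed_and_order_preserving(self, small_library):
        compounds = small_library[0][:30]
        m = similarity_matrix(compounds)
        order = ward_cluster(m)
        ids = [c.compound_id for c in compounds]
        cats = [Category.A if i % 2 else Category.E for i in range(30)]
        a = polar_layout(order, ids, cats, jitter_seed=11)
        b = polar_layout(order, ids, cats, jitter_seed=11)
        assert np.array_equal(a.angle, b.angle) and np.array_equal(a.radius, b.radius)
        # jitter must not reorder compounds along the circumference
        rank = np.argsort([list(order.leaf_order).index(i) for i in range(30)])
        angles_in_leaf_order = a.angle[order.leaf_order]
        assert np.all(np.diff(angles_in_leaf_order) > 0)

    def test_category_rings_are_distinct(self):
        order = ward_cluster(matrix(np.eye(6)))
        ids = [f"c{i}" for i in range(6)]
        cats = [Category.A] * 3 + [Category.E] * 3
        pl = polar_layout(order, ids, cats, jitter_seed=3)
        r_a, r_e = pl.radius[:3], pl.radius[3:]
        assert r_a.max() < r_e.min()  # rings A and E cannot overlap

    def test_unknown_category_rejected(self):
        order = ward_cluster(matrix(np.eye(2)))
        with pytest.raises(ValueError):
            polar_layout(order, ["a", "b"], [Category.A, "H"])


class TestNetwork:
    def test_threshold_is_strict(self):
        m = matrix([[1.0, 0.5], [0.5, 1.0]])
        assert build_network(m, 0.5).graph.number_of_edges() == 0
        m2 = matrix([[1.0, 0.5 + 1e-9], [0.5 + 1e-9, 1.0]])
        assert build_network(m2, 0.5).graph.number_of_edges() == 1

    def test_single_compound(self):
        net = build_network(matrix([[1.0]]))
        assert net.graph.number_of_nodes() == 1
        assert net.graph.number_of_edges() == 0

    def test_matches_bruteforce_thresholding(self, small_library):
        compounds = small_library[0]
        m = similarity_matrix(compounds)
        net = build_network(m, 0.5)
        expected = {
            frozenset((m.compound_ids[i], m.compound_ids[j]))
            for i in range(m.n)
            for j in range(m.n)
            if i < j and m.values[i, j] > 0.5
        }
        got = {frozenset(e) for e in net.graph.edges}
        assert got == expected
        assert all(u != v for u, v in net.graph.edges)


class TestClusters:
    def test_path_and_isolates(self):
        import networkx as nx

        from zfscreen.layout import SimilarityNetwork

        path = SimilarityNetwork(nx.path_graph(6), 0.5)
        assert extract_clusters(path) == [set(range(6))]
        isolates = SimilarityNetwork(nx.empty_graph(10), 0.5)
        assert extract_clusters(isolates) == []

    def test_min_size_filter_and_ordering(self):
        import networkx as nx

        from zfscreen.layout import SimilarityNetwork

        g = nx.Graph()
        g.add_edges_from([(i, i + 1) for i in range(6)])       # component of 7
        g.add_edges_from([(10, 11), (11, 12)])                  # component of 3
        clusters = extract_clusters(SimilarityNetwork(g, 0.5))
        assert clusters == [set(range(7))]


class TestHeatmapOrder:
    def test_descending_with_lexicographic_ties(self):
        recs = [
            TriageRecord("b", mbp_average=8.5),
            TriageRecord("c", mbp_average=4.0),
            TriageRecord("a", mbp_average=9.0),
            TriageRecord("e", mbp_average=4.0),
            TriageRecord("d", mbp_average=None),
        ]
        ordered = order_heatmap(recs)
        assert [r.compound_id for r in ordered] == ["a", "b", "c", "e", "d"]
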