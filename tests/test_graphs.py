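"""Thresholding and graph metrics against closed forms and independent oracles."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fcnet import (
    BinaryGraph,
    ConnectivityMatrix,
    SparsityGrid,
    assortativity,
    clustering_coefficient,
    eigenvector_centrality,
    metric_sweep,
    sparsity_threshold,
)
from fcnet.graphs import edge_count_for_sparsity

from .conftest import adjacency_from_edges, random_connectivity


def graph_from_edges(n, edges, sparsity=0.2):
    return BinaryGraph(
        adjacency=adjacency_from_edges(n, edges),
        region_labels=[f"R{i}" for i in range(n)],
        sparsity=sparsity,
    )


def random_graph(n, p, rng):
    A = (rng.random((n, n)) < p).astype(int)
    A = np.triu(A, 1)
    A += A.T
    return graph_from_edges(n, list(zip(*np.nonzero(np.triu(A, 1)))))


class TestThreshold:
    def test_116_regions_at_10_percent_gives_667_edges(self, rng):
        C = random_connectivity(116, rng)
        G = sparsity_threshold(C, 0.10)
        assert G.n_edges == 667 == edge_count_for_sparsity(116, 0.10)

    def test_top_three_of_six_pairs_selected(self):
        vals = np.eye(4)
        pairs = [(0, 1, 0.9), (0, 2, 0.8), (0, 3, 0.7), (1, 2, 0.6), (1, 3, 0.5), (2, 3, 0.4)]
        for i, j, v in pairs:
            vals[i, j] = vals[j, i] = v
        C = ConnectivityMatrix(values=vals, region_labels=list("ABCD"))
        G = sparsity_threshold(C, 0.5)
        assert set(G.edge_list()) == {(0, 1), (0, 2), (0, 3)}

    def test_edge_sets_nested_across_grid(self, rng):
        C = random_connectivity(30, rng)
        prev = set()
        for s in SparsityGrid():
            edges = set(sparsity_threshold(C, s).edge_list())
            assert prev <= edges
            prev = edges

    def test_matches_brute_force_ranking(self, rng):
        # independent oracle: sort all pairs by (-value, i, j), take top m
        C = random_connectivity(15, rng)
        s = 0.25
        m = edge_count_for_sparsity(15, s)
        pairs = sorted(
            ((i, j) for i in range(15) for j in range(i + 1, 15)),
            key=lambda ij: (-C.values[ij], ij),
        )
        expected = set(pairs[:m])
        assert set(sparsity_threshold(C, s).edge_list()) == expected

    def test_signed_vs_absolute_ranking(self):
        vals = np.eye(3)
        vals[0, 1] = vals[1, 0] = -0.95
        vals[0, 2] = vals[2, 0] = 0.30
        vals[1, 2] = vals[2, 1] = 0.10
        C = ConnectivityMatrix(values=vals, region_labels=list("XYZ"))
        assert set(sparsity_threshold(C, 0.34).edge_list()) == {(0, 2)}
        assert set(sparsity_threshold(C, 0.34, absolute=True).edge_list()) == {(0, 1)}

    def test_tied_values_break_deterministically(self):
        vals = np.full((5, 5), 0.5)
        np.fill_diagonal(vals, 1.0)
        C = ConnectivityMatrix(values=vals, region_labels=list("ABCDE"))
        first = sparsity_threshold(C, 0.3).edge_list()
        second = sparsity_threshold(C, 0.3).edge_list()
        assert first == second == [(0, 1), (0, 2), (0, 3)]

    @pytest.mark.parametrize("s", [0.0, 1.0, -0.1, 1.5])
    def test_sparsity_out_of_range(self, s, rng):
        with pytest.raises(ValueError):
            sparsity_threshold(random_connectivity(5, rng), s)


class TestClustering:
    def test_triangle_is_fully_clustered(self):
        G = graph_from_edges(3, [(0, 1), (0, 2), (1, 2)])
        per_node, mean = clustering_coefficient(G)
        np.testing.assert_allclose(per_node, 1.0)
        assert mean == 1.0

    def test_path_has_no_clustering(self):
        G = graph_from_edges(3, [(0, 1), (1, 2)])
        per_node, mean = clustering_coefficient(G)
        np.testing.assert_allclose(per_node, 0.0)
        assert mean == 0.0

    def test_triangle_with_pendant(self):
        # node C has degree 3 and one of its three neighbour pairs connected
        A, B, C, D = range(4)
        G = graph_from_edges(4, [(A, B), (A, C), (B, C), (C, D)])
        per_node, _ = clustering_coefficient(G)
        assert per_node[C] == pytest.approx(1 / 3)

    def test_complete_graph_mean_is_one_tree_is_zero(self, rng):
        K = graph_from_edges(6, [(i, j) for i in range(6) for j in range(i + 1, 6)])
        assert clustering_coefficient(K)[1] == 1.0
        tree = graph_from_edges(7, [(0, i) for i in range(1, 4)] + [(1, 4), (1, 5), (2, 6)])
        assert clustering_coefficient(tree)[1] == 0.0


class TestEigenvectorCentrality:
    def test_complete_graph_values_equal(self):
        G = graph_from_edges(4, [(i, j) for i in range(4) for j in range(i + 1, 4)])
        np.testing.assert_allclose(eigenvector_centrality(G), 0.5, atol=1e-9)

    def test_star_center_and_leaves(self):
        G = graph_from_edges(4, [(0, 1), (0, 2), (0, 3)])
        c = eigenvector_centrality(G)
        assert c[0] == pytest.approx(1 / np.sqrt(2), abs=1e-9)
        np.testing.assert_allclose(c[1:], 1 / np.sqrt(6), atol=1e-9)

    def test_isolated_node_gets_zero(self):
        G = graph_from_edges(4, [(0, 1), (0, 2), (1, 2)])
        assert eigenvector_centrality(G)[3] == pytest.approx(0.0, abs=1e-9)

    def test_edgeless_graph_all_zero(self):
        G = graph_from_edges(5, [])
        np.testing.assert_array_equal(eigenvector_centrality(G), 0.0)

    def test_matches_dense_eigensolver(self, rng):
        for _ in range(20):
            G = random_graph(12, 0.3, rng)
            if G.n_edges == 0:
                continue
            w, V = np.linalg.eigh(G.adjacency.astype(float))
            ref = np.abs(V[:, -1])
            np.testing.assert_allclose(eigenvector_centrality(G), ref, atol=1e-8)


class TestAssortativity:
    def test_star_is_maximally_disassortative(self):
        for leaves in (3, 5, 9):
            G = graph_from_edges(leaves + 1, [(0, i) for i in range(1, leaves + 1)])
            assert assortativity(G) == pytest.approx(-1.0)

    def test_ring_is_undefined(self):
        G = graph_from_edges(5, [(i, (i + 1) % 5) for i in range(5)])
        assert np.isnan(assortativity(G))

    def test_edgeless_graph_raises(self):
        with pytest.raises(ValueError):
            assortativity(graph_from_edges(3, []))

    def test_matches_edge_list_oracle(self, rng):
        # independent oracle: explicit correlation over the directed edge list
        for _ in range(25):
            G = random_graph(15, 0.3, rng)
            k = G.degrees()
            pts = [(k[i], k[j]) for i, j in G.edge_list()]
            pts += [(b, a) for a, b in pts]
            x, y = np.array(pts, dtype=float).T
            if x.std() == 0:
                continue
            expected = np.corrcoef(x, y)[0, 1]
            assert assortativity(G) == pytest.approx(expected, abs=1e-12)


class TestOracleEquivalence:
    def test_metrics_match_networkx_on_random_graphs(self, rng):
        """All three metrics agree with networkx within 1e-8 on 100 random graphs."""
        checked = 0
        while checked < 100:
            n = int(rng.integers(5, 31))
            G = random_graph(n, float(rng.uniform(0.15, 0.7)), rng)
            if G.n_edges < 2:
                continue
            H = nx.from_numpy_array(G.adjacency)
            per_node, mean_c = clustering_coefficient(G)
            nx_clust = nx.clustering(H)
            np.testing.assert_allclose(
                per_node, [nx_clust[i] for i in range(n)], atol=1e-8
            )
            assert mean_c == pytest.approx(np.mean(list(nx_clust.values())), abs=1e-8)
            try:
                nx_cent = nx.eigenvector_centrality_numpy(H)
            except Exception:
                continue
            ref = np.array([nx_cent[i] for i in range(n)])
            ref = np.abs(ref) / np.linalg.norm(ref)
            ours = eigenvector_centrality(G)
            # compare only when the dominant eigenvalue is well separated;
            # otherwise the eigenvector itself is not unique
            w = np.linalg.eigvalsh(G.adjacency.astype(float))
            if w[-1] - w[-2] > 1e-6:
                np.testing.assert_allclose(ours, ref, atol=1e-8)
            r = assortativity(G)
            if not np.isnan(r):
                assert r == pytest.approx(
                    nx.degree_assortativity_coefficient(H), abs=1e-8
                )
            checked += 1


class TestMetricSweep:
    def test_row_count_bookkeeping(self, rng):
        C = random_connectivity(10, rng)
        table = metric_sweep(C, subject_id="s1", session="pre")
        assert len(table) == 9 * (2 * 10 + 2)

    def test_relabeling_invariance(self, rng):
        C = random_connectivity(12, rng)
        perm = rng.permutation(12)
        C_perm = ConnectivityMatrix(
            values=C.values[np.ix_(perm, perm)],
            region_labels=[C.region_labels[i] for i in perm],
        )
        a = metric_sweep(C, [0.3]).set_index(["scope", "metric"])["value"]
        b = metric_sweep(C_perm, [0.3]).set_index(["scope", "metric"])["value"]
        for key in a.index:
            assert a[key] == pytest.approx(b[key], abs=1e-9), key

    def test_repeated_runs_identical_under_ties(self):
        vals = np.full((6, 6), 0.4)
        np.fill_diagonal(vals, 1.0)
        C = ConnectivityMatrix(values=vals, region_labels=list("ABCDEF"))
        t1 = metric_sweep(C)
        t2 = metric_sweep(C)
        assert t1.equals(t2)


@settings(max_examples=30, deadline=None)
@given(st.integers(min_value=3, max_value=20), st.integers(min_value=0, max_value=2**31 - 1))
def test_metric_ranges_on_arbitrary_graphs(n, seed):
    """Clustering in [0,1]; centrality non-negative with unit L2 norm."""
    rng = np.random.default_rng(seed)
    G = random_graph(n, 0.4, rng)
    per_node, mean_c = clustering_coefficient(G)
    assert ((per_node >= 0) & (per_node <= 1)).all()
    assert 0 <= mean_c <= 1
    cent = eigenvector_centrality(G)
    assert (cent >= 0).all()
    if G.n_edges:
        assert np.linalg.norm(cent) == pytest.approx(1.0)
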