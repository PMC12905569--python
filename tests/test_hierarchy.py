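"""Distances, UPGMA, weighted modularity, nulls, cuts, and comparisons."""
import numpy as np
import pytest
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from copanet import hierarchy
from copanet.errors import NodeSetMismatchError
from copanet.hierarchy import Partition
from conftest import block_similarity_network, make_network
from _oracles import cophenetic_matrix, naive_weighted_modularity, pair_counting_ari


class TestDistanceMatrix:
    def test_formula(self):
        net = make_network([("A", "B", 0.5), ("B", "C", 0.2)])
        nodes, d = hierarchy.distance_matrix(net)
        idx = {c: i for i, c in enumerate(nodes)}
        assert d[idx["A"], idx["B"]] == 0.0
        assert d[idx["B"], idx["C"]] == pytest.approx(0.3)
        assert d[idx["A"], idx["C"]] == pytest.approx(0.5)  # non-edge -> max(e)

    def test_uniform_weights(self):
        net = make_network([("A", "B", 0.4), ("C", "D", 0.4)])
        nodes, d = hierarchy.distance_matrix(net)
        idx = {c: i for i, c in enumerate(nodes)}
        assert d[idx["A"], idx["B"]] == 0.0
        assert d[idx["A"], idx["C"]] == pytest.approx(0.4)

    def test_single_edge(self):
        net = make_network([("A", "B", 0.7)], nodes=["A", "B", "C"])
        nodes, d = hierarchy.distance_matrix(net)
        idx = {c: i for i, c in enumerate(nodes)}
        assert d[idx["A"], idx["B"]] == 0.0
        assert d[idx["A"], idx["C"]] == pytest.approx(0.7)
        assert np.allclose(np.diag(d), 0.0)

    def test_edgeless_raises(self):
        net = make_network([], nodes=["A", "B"])
        with pytest.raises(ValueError):
            hierarchy.distance_matrix(net)


class TestAverageLinkage:
    def test_forced_merge_order(self):
        nodes = ["A", "B", "C"]
        d = np.array([[0, 1, 3], [1, 0, 3], [3, 3, 0]], dtype=float)
        dend = hierarchy.average_linkage(nodes, d)
        assert dend.merges[0, 2] == 1.0 and dend.merges[0, 3] == 2
        assert dend.merges[1, 2] == 3.0 and dend.merges[1, 3] == 3

    def test_pairs_merge_before_cross(self):
        nodes = list("ABCD")
        d = np.full((4, 4), 10.0)
        np.fill_diagonal(d, 0.0)
        d[0, 1] = d[1, 0] = 1.0
        d[2, 3] = d[3, 2] = 2.0
        dend = hierarchy.average_linkage(nodes, d)
        assert list(dend.merges[:2, 2]) == [1.0, 2.0]
        assert dend.merges[2, 2] == 10.0

    def test_upgma_average_by_hand(self):
        # d(A,B)=1, d(A,C)=2, d(B,C)=4 -> final height (2+4)/2 = 3
        nodes = ["A", "B", "C"]
        d = np.array([[0, 1, 2], [1, 0, 4], [2, 4, 0]], dtype=float)
        dend = hierarchy.average_linkage(nodes, d)
        assert dend.merges[1, 2] == pytest.approx(3.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_scipy_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        n = 9
        condensed = rng.random(n * (n - 1) // 2) + 0.01  # distinct, no ties
        d = squareform(condensed)
        nodes = [f"n{i}" for i in range(n)]
        dend = hierarchy.average_linkage(nodes, d)
        ours = cophenetic_matrix(dend.leaves, dend.merges)
        ref = squareform(cophenet(linkage(condensed, method="average")))
        order = [dend.leaves.index(c) for c in nodes]
        assert np.allclose(ours[np.ix_(order, order)], ref, atol=1e-10)

    def test_tie_break_lexicographic(self):
        nodes = ["B", "A", "C"]
        d = np.ones((3, 3)) - np.eye(3)  # all distances tied
        dend = hierarchy.average_linkage(nodes, d)
        # first merge must involve A and B (lexicographically first codes)
        assert set(dend.leaves[int(i)] for i in dend.merges[0, :2]) == {"A", "B"}

    def test_newick_roundtrip_with_dendropy(self):
        import dendropy

        net = make_network([("A", "B", 0.5), ("B", "C", 0.2), ("C", "D", 0.4)])
        nodes, d = hierarchy.distance_matrix(net)
        dend = hierarchy.average_linkage(nodes, d)
        tree = dendropy.Tree.get(data=dend.to_newick(), schema="newick")
        assert {leaf.taxon.label for leaf in tree.leaf_node_iter()} == set("ABCD")


class TestWeightedModularity:
    def test_single_cluster_is_zero(self, two_triangle_network):
        part = Partition(dict.fromkeys(two_triangle_network.nodes, 0))
        assert hierarchy.weighted_modularity(
            two_triangle_network, part) == pytest.approx(0.0, abs=1e-12)

    def test_two_triangles_with_bridge(self, two_triangle_network):
        part = Partition({"a1": 0, "a2": 0, "a3": 0, "b1": 1, "b2": 1, "b3": 1})
        q = hierarchy.weighted_modularity(two_triangle_network, part)
        assert q == pytest.approx(5 / 14, abs=1e-12)

    def test_triangle_all_singletons(self):
        net = make_network([("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 1.0)])
        part = Partition({"a": 0, "b": 1, "c": 2})
        assert hierarchy.weighted_modularity(net, part) == pytest.approx(
            -1 / 3, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        nodes = [f"n{i}" for i in range(8)]
        edges = {}
        for i in range(8):
            for j in range(i + 1, 8):
                if rng.random() < 0.45:
                    edges[(nodes[i], nodes[j])] = float(rng.random()) + 0.05
        if not edges:
            pytest.skip("empty draw")
        net = make_network([(a, b, w) for (a, b), w in edges.items()],
                           nodes=nodes)
        labels = {n: int(rng.integers(0, 3)) for n in nodes}
        q = hierarchy.weighted_modularity(net, Partition(labels))
        oracle = naive_weighted_modularity(nodes, edges, labels)
        assert q == pytest.approx(oracle, abs=1e-12)

    def test_partition_must_cover_nodes(self, two_triangle_network):
        with pytest.raises(NodeSetMismatchError):
            hierarchy.weighted_modularity(two_triangle_network,
                                          Partition({"a1": 0}))


class TestRewireWeighted:
    def test_complete_graph_unchanged(self):
        nodes = list("abcd")
        edges = [(a, b, 1.0) for i, a in enumerate(nodes)
                 for b in nodes[i + 1:]]
        net = make_network(edges)
        with pytest.warns(Warning):
            out = hierarchy.rewire_weighted(net, seed=0)
        assert out.rigid and out.edge_set() == net.edge_set()

    @pytest.mark.parametrize("seed", range(5))
    def test_degrees_and_weight_multiset_preserved(self, seed):
        rng = np.random.default_rng(seed)
        net, _ = block_similarity_network(rng)
        out = hierarchy.rewire_weighted(net, seed=seed)
        deg = lambda n: sorted(d for _, d in n.graph.degree)
        weights = lambda n: sorted(d["weight"]
                                   for *_, d in n.graph.edges(data=True))
        assert deg(out) == deg(net)
        assert np.allclose(weights(out), weights(net))
        assert out.n_edges == net.n_edges

    def test_four_cycle_rearrangement(self):
        edges = [("a", "b", 0.1), ("b", "c", 0.2), ("c", "d", 0.3),
                 ("a", "d", 0.4)]
        net = make_network(edges)
        seen = set()
        for seed in range(12):
            out = hierarchy.rewire_weighted(net, seed=seed)
            assert sorted(d for _, d in out.graph.degree) == [2, 2, 2, 2]
            ws = sorted(d["weight"] for *_, d in out.graph.edges(data=True))
            assert ws == [0.1, 0.2, 0.3, 0.4]
            seen.add(frozenset(out.edge_set()))
        # the 4-cycle space on 4 labeled nodes has 3 distinct topologies
        assert len(seen) >= 2


class TestNormalizedModularity:
    def test_single_cluster_delta_zero(self, two_triangle_network):
        part = Partition(dict.fromkeys(two_triangle_network.nodes, 0))
        res = hierarchy.normalized_modularity(two_triangle_network, part,
                                              n_null=50, seed=0)
        assert res.q_w == pytest.approx(0.0, abs=1e-12)
        assert res.delta_q == pytest.approx(0.0, abs=1e-12)

    def test_rigid_complete_graph_delta_zero(self):
        nodes = list("abcde")
        net = make_network([(a, b, 1.0) for i, a in enumerate(nodes)
                            for b in nodes[i + 1:]])
        part = Partition({"a": 0, "b": 0, "c": 1, "d": 1, "e": 1})
        with pytest.warns(Warning):
            res = hierarchy.normalized_modularity(net, part, n_null=20, seed=1)
        assert res.delta_q == pytest.approx(0.0, abs=1e-12)

    def test_planted_cliques_strongly_modular(self):
        edges = [(a, b, 1.0) for grp in ("abcd", "efgh")
                 for i, a in enumerate(grp) for b in grp[i + 1:]]
        edges.append(("d", "e", 1.0))
        net = make_network(edges)
        part = Partition({c: 0 if c in "abcd" else 1 for c in "abcdefgh"})
        res = hierarchy.normalized_modularity(net, part, n_null=300, seed=3)
        # null SE from re-deriving the ensemble spread
        _, ou, ov, ow = hierarchy.null_ensemble(net, n_null=300, seed=3)
        eu, ev, w = net.edge_arrays(net.nodes)
        qs = hierarchy._null_qs(ou, ov, ow,
                                part.label_vector(net.nodes), 2 * w.sum())
        se = qs.std() / np.sqrt(len(qs))
        assert res.delta_q > 3 * se > 0


class TestOptimalCut:
    def test_recovers_two_separated_blocks(self):
        rng = np.random.default_rng(7)
        net, blocks = block_similarity_network(rng, n_blocks=2, block_size=5,
                                               w_in=0.6, w_out=0.05, p_out=0.3)
        nodes, d = hierarchy.distance_matrix(net)
        dend = hierarchy.average_linkage(nodes, d)
        part, res = hierarchy.optimal_cut(dend, net, n_null=200, seed=1)
        truth = Partition({c: k for k, blk in enumerate(blocks) for c in blk})
        ari, _ = hierarchy.compare_partitions(part, truth)
        assert ari == 1.0
        assert res.delta_q > 0

    def test_uniform_clique_ties_to_single_cluster(self):
        nodes = list("abcd")
        net = make_network([(a, b, 0.5) for i, a in enumerate(nodes)
                            for b in nodes[i + 1:]])
        nodes_, d = hierarchy.distance_matrix(net)
        dend = hierarchy.average_linkage(nodes_, d)
        with pytest.warns(Warning):
            part, res = hierarchy.optimal_cut(dend, net, n_null=20, seed=0)
        assert part.n_clusters == 1
        assert res.delta_q == pytest.approx(0.0, abs=1e-12)

    def test_isolate_reported_unclustered(self):
        rng = np.random.default_rng(3)
        net, blocks = block_similarity_network(rng, n_blocks=2, block_size=4)
        net.graph.add_node("Z9.lonely")
        nodes, d = hierarchy.distance_matrix(net)
        dend = hierarchy.average_linkage(nodes, d)
        part, _ = hierarchy.optimal_cut(dend, net, n_null=100, seed=2)
        assert "Z9.lonely" in part.singletons()


class TestComparisons:
    def test_identical_partitions(self):
        p = Partition({"a": 0, "b": 0, "c": 1})
        assert hierarchy.compare_partitions(p, p) == (1.0, 1.0)

    def test_singletons_vs_lump_is_chance(self):
        p1 = Partition({c: i for i, c in enumerate("abcd")})
        p2 = Partition(dict.fromkeys("abcd", 0))
        ari, _ = hierarchy.compare_partitions(p1, p2)
        assert ari == pytest.approx(0.0, abs=1e-12)

    def test_cross_partition_matches_pair_counting(self):
        p1 = Partition({"A": 0, "B": 0, "C": 1, "D": 1})
        p2 = Partition({"A": 0, "C": 0, "B": 1, "D": 1})
        ari, _ = hierarchy.compare_partitions(p1, p2)
        nodes = sorted(p1.labels)
        oracle = pair_counting_ari(p1.label_vector(nodes), p2.label_vector(nodes))
        assert ari == pytest.approx(oracle, abs=1e-12)

    def test_node_mismatch_raises(self):
        with pytest.raises(NodeSetMismatchError):
            hierarchy.compare_partitions(Partition({"a": 0}),
                                         Partition({"b": 0}))

    def test_edge_overlap_identical_and_disjoint(self):
        n1 = make_network([("A", "B", 1), ("B", "C", 1)])
        assert hierarchy.edge_overlap(n1, n1)[0] == 1.0
        n2 = make_network([("A", "C", 1)], nodes=["A", "B", "C"])
        assert hierarchy.edge_overlap(n1, n2)[0] == 0.0

    def test_edge_overlap_counts(self):
        n1 = make_network([("A", "B", 1), ("B", "C", 1)], nodes=list("ABCD"))
        n2 = make_network([("A", "B", 1), ("C", "D", 1)], nodes=list("ABCD"))
        jac, (f1, f2) = hierarchy.edge_overlap(n1, n2)
        assert jac == pytest.approx(1 / 3)
        assert (f1, f2) == (0.5, 0.5)

    def test_both_empty_raises(self):
        n = make_network([], nodes=["A", "B"])
        with pytest.raises(ValueError):
            hierarchy.edge_overlap(n, n)
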