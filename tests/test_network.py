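"""Sociogram construction, centrality/subgroup metrics vs independent oracles.

Oracles: scipy's Floyd-Warshall for geodesic distances (farness), a
pure-python BFS geodesic enumerator for betweenness, node-removal brute
force for cutpoints, and igraph for biconnected blocks. The implementation
under test uses networkx; the oracles do not.
"""

import itertools

import igraph
import networkx as nx
import numpy as np
import pytest
from scipy.sparse.csgraph import floyd_warshall

from proxnet.association import SignedAssociation, associate, sign_split
from proxnet.neighbors import NNCountMatrix
from proxnet.network import (
    betweenness,
    blocks,
    build_graph,
    closeness,
    cutpoints,
    degree,
    density,
    export_graph,
    farness,
    graph_from_weight_matrix,
    import_graph,
    node_table,
)


def assoc_from_sr(sr, names, threshold=1.96):
    sr = np.asarray(sr, dtype=float)
    pos, neg = sign_split(sr, threshold)
    return SignedAssociation(
        individuals=list(names),
        observed=np.zeros_like(sr, dtype=int),
        expected=np.zeros_like(sr),
        sr=sr,
        positive=pos,
        negative=neg,
        threshold=threshold,
        n=0,
    )


def random_graph(rng, n=None, p=None):
    n = n or int(rng.integers(2, 13))
    p = p if p is not None else float(rng.uniform(0.1, 0.6))
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(i, j)
    return g


def brute_betweenness(g):
    """Fractional geodesic credit from explicit BFS path enumeration."""
    nodes = list(g.nodes)
    adj = {v: set(g.neighbors(v)) for v in nodes}
    out = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        # BFS distances from s
        dist = {s: 0}
        frontier = [s]
        while frontier:
            nxt = []
            for u in frontier:
                for w in adj[u]:
                    if w not in dist:
                        dist[w] = dist[u] + 1
                        nxt.append(w)
            frontier = nxt
        if t not in dist:
            continue
        paths = []

        def extend(path):
            u = path[-1]
            if u == t:
                paths.append(path)
                return
            for w in adj[u]:
                if dist.get(w, -1) == dist[u] + 1 and dist[w] <= dist[t]:
                    extend(path + [w])

        extend([s])
        for path in paths:
            for v in path[1:-1]:
                out[v] += 1.0 / len(paths)
    return out


class TestBuildGraph:
    def test_one_way_edge_from_single_passing_direction(self):
        sr = np.zeros((2, 2))
        sr[0, 1] = 2.5
        g = build_graph(assoc_from_sr(sr, ["A", "B"]), "positive")
        assert g.number_of_edges() == 1
        assert g["A"]["B"]["weight"] == 2.5
        assert g["A"]["B"]["direction"] == "one-way"

    def test_no_significant_cells_gives_edgeless_graph_with_all_nodes(self):
        g = build_graph(assoc_from_sr(np.zeros((4, 4)), list("ABCD")), "positive")
        assert g.number_of_edges() == 0 and g.number_of_nodes() == 4

    def test_two_way_annotation_and_max_weight(self):
        sr = np.zeros((2, 2))
        sr[0, 1], sr[1, 0] = 2.2, 3.1
        g = build_graph(assoc_from_sr(sr, ["A", "B"]), "positive")
        assert g["A"]["B"]["direction"] == "two-way"
        assert g["A"]["B"]["weight"] == 3.1
        assert g["A"]["B"]["arrows"] == "A->B;B->A"

    def test_negative_graph_uses_negated_weights(self):
        sr = np.zeros((2, 2))
        sr[0, 1] = -4.0
        g = build_graph(assoc_from_sr(sr, ["A", "B"]), "negative")
        assert g["A"]["B"]["weight"] == 4.0


class TestDensity:
    def test_complete_and_edgeless(self):
        assert density(nx.complete_graph(5)) == 1.0
        g = nx.Graph()
        g.add_nodes_from(range(4))
        assert density(g) == 0.0

    def test_counting_oracle_on_random_graphs(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            g = random_graph(rng)
            n = g.number_of_nodes()
            assert density(g) == pytest.approx(g.number_of_edges() / (n * (n - 1) / 2))

    def test_single_node_raises(self):
        with pytest.raises(ValueError):
            density(nx.path_graph(1))


class TestPathComponentWorkedExample:
    """A four-node path inside a 15-node network, the rest unreachable."""

    @pytest.fixture
    def bear_like(self):
        g = nx.Graph()
        g.add_nodes_from(range(1, 16))
        g.add_edges_from([(11, 12), (12, 13), (13, 14)])
        # a second, denser component so node 2 stays fully isolated
        g.add_edges_from([(1, 4), (4, 5), (1, 5), (1, 9), (9, 10), (4, 10), (6, 7), (6, 15), (7, 15), (1, 6), (4, 8), (1, 8)])
        return g

    def test_path_degrees(self, bear_like):
        deg = degree(bear_like)
        assert [deg[v] for v in (11, 12, 13, 14)] == [1, 2, 2, 1]
        assert deg[2] == 0

    def test_betweenness_of_path_interior_is_two(self, bear_like):
        btw = betweenness(bear_like)
        assert btw[12] == 2.0 and btw[13] == 2.0
        assert btw[11] == 0.0 and btw[14] == 0.0

    def test_farness_unreachable_counts_as_n(self, bear_like):
        far = farness(bear_like)
        assert far[2] == 14 * 15  # isolated: 210
        assert far[11] == 1 + 2 + 3 + 11 * 15  # path endpoint: 171
        assert far[12] == 1 + 1 + 2 + 11 * 15  # path interior: 169

    def test_farness_alternative_convention(self, bear_like):
        far = farness(bear_like, unreachable="n-1")
        assert far[2] == 14 * 14

    def test_cutpoints_are_the_path_interior(self, bear_like):
        cut = cutpoints(bear_like)
        assert cut[12] == 1 and cut[13] == 1
        assert cut[11] == 0 and cut[14] == 0 and cut[2] == 0

    def test_blocks_of_the_path(self, bear_like):
        blk = blocks(bear_like)
        assert [11, 12] in blk and [12, 13] in blk and [13, 14] in blk

    def test_closeness_is_reciprocal_farness(self, bear_like):
        far, close = farness(bear_like), closeness(bear_like)
        for v in bear_like.nodes:
            assert close[v] == pytest.approx(1.0 / far[v])


class TestMetricOracles:
    def test_farness_matches_floyd_warshall(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            g = random_graph(rng)
            n = g.number_of_nodes()
            adj = nx.to_numpy_array(g, nodelist=sorted(g.nodes))
            dist = floyd_warshall(adj, unweighted=True)
            dist[np.isinf(dist)] = n
            far = farness(g)
            for k, v in enumerate(sorted(g.nodes)):
                assert far[v] == pytest.approx(dist[k].sum())

    def test_betweenness_matches_geodesic_enumeration(self):
        rng = np.random.default_rng(6)
        for _ in range(15):
            g = random_graph(rng, n=int(rng.integers(2, 9)))
            oracle = brute_betweenness(g)
            btw = betweenness(g)
            for v in g.nodes:
                assert btw[v] == pytest.approx(oracle[v])

    def test_star_center_betweenness_closed_form(self):
        for k in (3, 5, 8):
            g = nx.star_graph(k)  # node 0 is the hub
            assert betweenness(g)[0] == k * (k - 1) / 2

    def test_tree_betweenness_sums_to_path_length_excess(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            tree = nx.random_labeled_tree(int(rng.integers(3, 12)), seed=int(rng.integers(1 << 30)))
            total = sum(betweenness(tree).values())
            excess = sum(
                nx.shortest_path_length(tree, s, t) - 1 for s, t in itertools.combinations(tree.nodes, 2)
            )
            assert total == pytest.approx(excess)

    def test_cutpoints_match_node_removal_brute_force(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            g = random_graph(rng)
            cut = cutpoints(g)
            before = nx.number_connected_components(g)
            for v in g.nodes:
                rest = g.subgraph([u for u in g.nodes if u != v])
                after = nx.number_connected_components(rest)
                # isolated nodes vanish without splitting anything
                expected = after > before if g.degree(v) > 0 else False
                assert bool(cut[v]) == expected

    def test_blocks_match_igraph_and_structural_invariants(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            g = random_graph(rng)
            blk = blocks(g)
            ig = igraph.Graph(n=g.number_of_nodes(), edges=list(g.edges))
            ig_blocks = sorted(sorted(b) for b in ig.biconnected_components())
            assert sorted(sorted(b) for b in blk) == ig_blocks
            # every edge lies in exactly one block
            for u, v in g.edges:
                containing = [b for b in blk if u in b and v in b]
                assert len(containing) == 1
            # two blocks intersect only in cutpoints
            cut = {v for v, flag in cutpoints(g).items() if flag}
            for b1, b2 in itertools.combinations(blk, 2):
                assert set(b1) & set(b2) <= cut


class TestNodeTable:
    def test_cutpoint_average_is_a_proportion(self):
        # 9 nodes, two articulation nodes -> average cutpoint 2/9 = 0.22:
        # a 7-cycle core with one pendant on each of two core nodes
        g = nx.cycle_graph(7)
        g.add_edges_from([(0, 7), (1, 8)])
        table = node_table(g)
        assert table.loc["Average", "cutpoint"] == pytest.approx(2 / 9)
        assert round(table.loc["Average", "cutpoint"], 2) == 0.22

    def test_edgeless_graph_all_zero_degree(self):
        g = nx.Graph()
        g.add_nodes_from("abcd")
        table = node_table(g)
        assert (table.loc[list("abcd"), "degree"] == 0).all()

    def test_mean_degree_handshake_identity(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            g = random_graph(rng)
            table = node_table(g)
            assert table.loc["Average", "degree"] == pytest.approx(2 * g.number_of_edges() / g.number_of_nodes())


class TestExport:
    @pytest.fixture
    def signed_graph(self):
        sr = np.zeros((4, 4))
        sr[0, 1], sr[1, 2], sr[2, 3], sr[2, 1] = 2.5, 3.0, 2.1, 2.2
        return build_graph(assoc_from_sr(sr, list("ABCD")), "positive")

    def test_graphml_roundtrip(self, tmp_path, signed_graph):
        path = tmp_path / "g.graphml"
        export_graph(signed_graph, path, "graphml")
        back = import_graph(path, "graphml")
        assert set(back.nodes) == set(signed_graph.nodes)
        assert set(map(frozenset, back.edges)) == set(map(frozenset, signed_graph.edges))
        assert back["B"]["C"]["direction"] == "two-way"
        assert back["A"]["B"]["weight"] == pytest.approx(2.5)

    def test_edgelist_roundtrip_keeps_isolates(self, tmp_path):
        sr = np.zeros((3, 3))
        sr[0, 1] = 2.5
        g = build_graph(assoc_from_sr(sr, list("ABC")), "positive")
        path = tmp_path / "g.csv"
        export_graph(g, path, "edgelist")
        back = import_graph(path, "edgelist")
        assert set(back.nodes) == {"A", "B", "C"}
        assert back["A"]["B"]["weight"] == 2.5

    def test_dot_export_and_unknown_format(self, tmp_path, signed_graph):
        export_graph(signed_graph, tmp_path / "g.dot", "dot")
        assert '"B" -- "C"' in (tmp_path / "g.dot").read_text()
        with pytest.raises(ValueError):
            export_graph(signed_graph, tmp_path / "g.xyz", "xyz")

    def test_signed_pair_export(self, tmp_path):
        sr = np.zeros((3, 3))
        sr[0, 1], sr[1, 2] = 2.5, -2.5
        assoc = assoc_from_sr(sr, list("ABC"))
        for sign in ("positive", "negative"):
            export_graph(build_graph(assoc, sign), tmp_path / f"net.{sign[:3]}.graphml", "graphml")
        pos = import_graph(tmp_path / "net.pos.graphml")
        neg = import_graph(tmp_path / "net.neg.graphml")
        assert pos.number_of_edges() == 1 and neg.number_of_edges() == 1


def test_graph_from_weight_matrix_matches_build_graph():
    rng = np.random.default_rng(10)
    counts = rng.poisson(9.0, size=(6, 6))
    np.fill_diagonal(counts, 0)
    names = [f"I{k}" for k in range(6)]
    a = associate(NNCountMatrix(names, counts, int(counts.sum())))
    g1 = build_graph(a, "positive")
    g2 = graph_from_weight_matrix(a.matrix("positive"), "positive")
    assert set(g1.edges) == set(g2.edges)
    for u, v in g1.edges:
        assert g1[u][v]["weight"] == pytest.approx(g2[u][v]["weight"])
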