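import itertools
from collections import deque

import networkx as nx
import numpy as np
import pytest

from plaquehub import ppi, synthetic
from plaquehub.errors import InputError
from plaquehub.ppi import McodeParams

from conftest import make_edges


# ---------------------------------------------------------------- oracle
def enumerate_shortest_paths(g, s, t):
    """All geodesics s->t by BFS predecessor DAG + backward DFS."""
    dist = {s: 0}
    preds = {s: []}
    q = deque([s])
    while q:
        u = q.popleft()
        for v in g.neighbors(u):
            if v not in dist:
                dist[v] = dist[u] + 1
                preds[v] = [u]
                q.append(v)
            elif dist[v] == dist[u] + 1:
                preds[v].append(u)
    if t not in dist:
        return []
    paths = []

    def walk(node, acc):
        if node == s:
            paths.append([s, *reversed(acc)])
            return
        for p in preds[node]:
            walk(p, acc + [node])

    walk(t, [])
    return paths


def centrality_oracle(g):
    """Betweenness/closeness by explicit geodesic enumeration."""
    bet = {v: 0.0 for v in g.nodes}
    clo = {}
    for comp in nx.connected_components(g):
        comp = sorted(comp)
        n = len(comp)
        for s, t in itertools.combinations(comp, 2):
            paths = enumerate_shortest_paths(g, s, t)
            for path in paths:
                for v in path[1:-1]:
                    bet[v] += 1.0 / len(paths)
        scale = (n - 1) * (n - 2) / 2.0
        for v in comp:
            bet[v] = bet[v] / scale if scale > 0 else 0.0
            if n > 1:
                total = sum(len(enumerate_shortest_paths(g, v, u)[0]) - 1
                            for u in comp if u != v)
                clo[v] = (n - 1) / total
            else:
                clo[v] = 0.0
    return bet, clo


# ---------------------------------------------------------------- graph build
class TestBuildGraph:
    def test_threshold_inclusive_at_400(self):
        g = ppi.build_graph(make_edges([("A", "B", 400), ("A", "C", 399)]))
        assert set(g.edges) == {("A", "B")}
        assert "C" not in g

    def test_self_loop_dropped(self):
        with pytest.raises(InputError):
            ppi.build_graph(make_edges([("A", "A", 900)]))

    def test_duplicate_keeps_max_confidence(self):
        g = ppi.build_graph(make_edges([("A", "B", 500), ("B", "A", 700)]))
        assert g["A"]["B"]["confidence"] == 700
        assert g.number_of_edges() == 1


# ---------------------------------------------------------------- MCODE
def clique_edges(nodes):
    return [(a, b) for a, b in itertools.combinations(nodes, 2)]


class TestMcodeWeights:
    def test_five_clique_weight(self):
        g = ppi.build_graph(make_edges(clique_edges("ABCDE")))
        w = ppi.mcode_vertex_weights(g)
        assert all(w[v] == pytest.approx(4.0) for v in "ABCDE")

    def test_low_degree_zero(self):
        g = ppi.build_graph(make_edges([("A", "B"), ("B", "C"), ("A", "C"), ("C", "D")]))
        w = ppi.mcode_vertex_weights(g)
        assert w["D"] == 0.0
        assert w["A"] == 0.0  # degree 2 < cutoff 3


class TestMcodeClusters:
    def test_five_clique_with_pendant(self):
        g = ppi.build_graph(make_edges(clique_edges("ABCDE") + [("A", "P")]))
        res = ppi.mcode_find_clusters(g)
        assert res.clusters == [set("ABCDE")]
        assert res.scores[0] == pytest.approx(5.0)

    def test_triangle_has_no_three_core(self):
        g = ppi.build_graph(make_edges(clique_edges("ABC")))
        assert ppi.mcode_find_clusters(g).clusters == []

    def test_bridged_four_cliques_split(self):
        g = ppi.build_graph(
            make_edges(clique_edges("ABCD") + clique_edges("EFGH") + [("D", "E")])
        )
        res = ppi.mcode_find_clusters(g)
        assert sorted(map(sorted, res.clusters)) == [list("ABCD"), list("EFGH")]

    def test_clusters_disjoint_and_contain_k_core(self):
        edges, _ = synthetic.synth_ppi(60, [6, 5, 4], 0.05, seed=11)
        g = ppi.build_graph(edges)
        res = ppi.mcode_find_clusters(g)
        seen = set()
        for cluster, score in zip(res.clusters, res.scores):
            assert not (cluster & seen)
            seen |= cluster
            sub = g.subgraph(cluster)
            assert nx.k_core(nx.Graph(sub), 3).number_of_nodes() > 0
            n, e = sub.number_of_nodes(), sub.number_of_edges()
            assert score == pytest.approx(2 * e / (n * (n - 1)) * n)

    def test_planted_cliques_recovered(self):
        """Planted modules come back with Jaccard >= 0.8 in every seed."""
        def jacc(a, b):
            return len(a & b) / len(a | b)

        for seed in range(20):
            edges, truth = synthetic.synth_ppi(50, [8, 5, 4], 0.01, seed)
            g = ppi.build_graph(edges)
            res = ppi.mcode_find_clusters(g)
            for mod in truth.planted_modules:
                best = max((jacc(mod, c) for c in res.clusters), default=0.0)
                assert best >= 0.8, f"seed {seed}: module of {len(mod)} lost ({best:.2f})"


# ---------------------------------------------------------------- centralities
class TestCentralities:
    def test_path_graph(self):
        g = ppi.build_graph(make_edges([("A", "B"), ("B", "C")]))
        topo = ppi.centralities(g)
        assert topo.loc["B", "betweenness"] == pytest.approx(1.0)
        assert topo.loc["B", "closeness"] == pytest.approx(1.0)
        assert topo.loc["A", "closeness"] == pytest.approx(2 / 3)

    def test_four_cycle_tied_geodesics(self):
        g = ppi.build_graph(make_edges([("A", "B"), ("B", "C"), ("C", "D"), ("D", "A")]))
        topo = ppi.centralities(g)
        assert np.allclose(topo["betweenness"], 0.5 / 3)

    def test_star(self):
        g = ppi.build_graph(make_edges([("C", f"L{i}") for i in range(5)]))
        topo = ppi.centralities(g)
        assert topo.loc["C", "betweenness"] == pytest.approx(1.0)
        assert topo.loc["C", "degree"] == 5

    def test_matches_enumeration_oracle_random_graphs(self):
        rng = np.random.default_rng(7)
        for trial in range(15):
            n = int(rng.integers(5, 31))
            p = 2.5 / n
            g = nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31)))
            g = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes})
            if g.number_of_edges() == 0:
                continue
            topo = ppi.centralities(g)
            bet, clo = centrality_oracle(g)
            for v in g.nodes:
                assert topo.loc[v, "betweenness"] == pytest.approx(bet[v], abs=1e-9)
                assert topo.loc[v, "closeness"] == pytest.approx(clo[v], abs=1e-9)
                assert topo.loc[v, "degree"] == g.degree[v]


# ---------------------------------------------------------------- hub ranking
class TestRankHubs:
    def test_dominant_node_first(self):
        g = ppi.build_graph(make_edges([("C", f"L{i}") for i in range(5)] + [("L0", "L1")]))
        topo = ppi.centralities(g)
        assert ppi.rank_hubs(topo, 1) == ["C"]

    def test_automorphic_tie_broken_by_id(self):
        g = ppi.build_graph(make_edges([("A", "B"), ("B", "C"), ("C", "D"), ("D", "A")]))
        topo = ppi.centralities(g)
        assert ppi.rank_hubs(topo, 4) == ["A", "B", "C", "D"]

    def test_planted_hub_recovered(self):
        hits = 0
        for seed in range(20):
            edges, truth = synthetic.synth_ppi(50, [8, 5, 4], 0.01, seed)
            g = ppi.build_graph(edges)
            topo = ppi.centralities(g)
            hits += ppi.rank_hubs(topo, 1)[0] == truth.hub_gene
        assert hits >= 19  # >= 95% of seeds
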