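"""PPI graph construction, MCODE module detection, centralities, hub ranking.

The graph is a simple undirected :class:`networkx.Graph` over gene
identifiers with a per-edge ``confidence`` attribute on the STRING 0-1000
scale.  Confidence acts purely as a construction filter; all path-based
quantities downstream use unweighted hop distances.

MCODE (molecular complex detection) is implemented from scratch:

1.  *Vertex weighting* — for each node v with degree >= degree_cutoff, take
    the closed neighbourhood N[v], find its highest k-core, and set
    weight(v) = k_max * density(highest k-core); lower-degree nodes get 0.
2.  *Complex prediction* — seeds are processed in decreasing weight order
    (ties: higher degree, then lexicographic id); from an unvisited seed,
    breadth-first inclusion of unvisited neighbours whose weight >=
    seed_weight * (1 - node_score_cutoff), up to max_depth hops.  A node
    joins at most one cluster.
3.  *Post-processing* — within each candidate cluster, edges supported by
    fewer than k_core - 2 common neighbours inside the cluster are pruned
    first (with the default 3-core such a lone bridge edge can never be
    part of any 3-core, so two dense complexes joined by a single edge
    split apart instead of merging); the cluster then separates into
    connected components, components lacking a k_core-core are discarded,
    and haircut iteratively removes within-cluster degree-1 nodes.  The
    cluster score is density * size, and clusters are reported in
    decreasing score order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import InputError
from .io_formats import EdgeTable


@dataclass
class McodeParams:
    degree_cutoff: int = 3
    node_score_cutoff: float = 0.4
    haircut: bool = True
    fluff: bool = False
    fluff_density: float = 0.2  # unused while fluff is off
    k_core: int = 3
    max_depth: int = 80


@dataclass
class ModuleResult:
    clusters: list[set[str]] = field(default_factory=list)
    scores: list[float] = field(default_factory=list)
    seed_nodes: list[str] = field(default_factory=list)


def build_graph(edges: EdgeTable, min_confidence: int = 400) -> nx.Graph:
    """Simple graph from scored edges: threshold, de-loop, de-duplicate.

    Keeps edges with confidence >= min_confidence (the printed "score >
    0.4" maps to the STRING-conventional inclusive 400), drops self-loops,
    collapses duplicates keeping the maximum confidence.  Isolated nodes
    never appear since nodes exist only through retained edges.
    """
    g = nx.Graph()
    for rec in edges.records.itertuples(index=False):
        if rec.gene_a == rec.gene_b:
            continue
        if rec.confidence < min_confidence:
            continue
        a, b, conf = rec.gene_a, rec.gene_b, int(rec.confidence)
        if g.has_edge(a, b):
            if conf > g[a][b]["confidence"]:
                g[a][b]["confidence"] = conf
        else:
            g.add_edge(a, b, confidence=conf)
    if g.number_of_nodes() == 0:
        raise InputError("no edges survive the confidence threshold")
    return g


def _density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def _highest_k_core(g: nx.Graph) -> tuple[int, nx.Graph]:
    """The maximum k with a non-empty k-core, and that core subgraph."""
    if g.number_of_nodes() == 0:
        return 0, g
    core_num = nx.core_number(g)
    k_max = max(core_num.values())
    core = g.subgraph([v for v, k in core_num.items() if k >= k_max])
    return k_max, core


def mcode_vertex_weights(g: nx.Graph, params: McodeParams | None = None) -> dict[str, float]:
    """Bader-Hogue core-clustering vertex weights."""
    params = params or McodeParams()
    weights: dict[str, float] = {}
    for v in g.nodes:
        if g.degree[v] < params.degree_cutoff:
            weights[v] = 0.0
            continue
        closed = g.subgraph([v, *g.neighbors(v)])
        k_max, core = _highest_k_core(closed)
        weights[v] = float(k_max) * _density(core)
    return weights


def _postprocess_cluster(
    g: nx.Graph, members: set[str], params: McodeParams
) -> list[set[str]]:
    """Bridge-prune, split, k-core filter and haircut one candidate cluster."""
    sub = nx.Graph(g.subgraph(members))
    # junction pruning: inside a clique of size >= k_core+1 (the densest unit
    # a k_core-core filter targets) every edge has >= k_core-1 common
    # neighbours, while bridges between two such complexes have fewer; edges
    # below that support are cut so complexes joined at a sparse junction
    # split instead of merging.  Triangle-free complexes are a known casualty.
    need = params.k_core - 1
    if need > 0:
        drop = [
            (a, b)
            for a, b in sub.edges
            if len(set(sub[a]) & set(sub[b])) < need
        ]
        sub.remove_edges_from(drop)
    out = []
    for comp in nx.connected_components(sub):
        comp_g = nx.Graph(sub.subgraph(comp))
        if nx.k_core(comp_g, params.k_core).number_of_nodes() == 0:
            continue
        if params.haircut:
            while True:
                leaves = [v for v in comp_g.nodes if comp_g.degree[v] <= 1]
                if not leaves:
                    break
                comp_g.remove_nodes_from(leaves)
        if comp_g.number_of_nodes() >= params.k_core:
            out.append(set(comp_g.nodes))
    return out


def mcode_find_clusters(g: nx.Graph, params: McodeParams | None = None) -> ModuleResult:
    """Seeded expansion over the vertex weights, then post-processing."""
    params = params or McodeParams()
    weights = mcode_vertex_weights(g, params)
    order = sorted(g.nodes, key=lambda v: (-weights[v], -g.degree[v], v))
    visited: set[str] = set()
    raw: list[tuple[set[str], str]] = []
    for seed in order:
        if seed in visited:
            continue
        threshold = weights[seed] * (1.0 - params.node_score_cutoff)
        members = {seed}
        visited.add(seed)
        frontier = [seed]
        depth = 0
        while frontier and depth < params.max_depth:
            nxt = []
            for u in frontier:
                for w in g.neighbors(u):
                    if w in visited:
                        continue
                    if weights[w] >= threshold:
                        visited.add(w)
                        members.add(w)
                        nxt.append(w)
            frontier = nxt
            depth += 1
        if len(members) > 1:
            raw.append((members, seed))
    clusters: list[set[str]] = []
    seeds: list[str] = []
    for members, seed in raw:
        for comp in _postprocess_cluster(g, members, params):
            clusters.append(comp)
            seeds.append(seed if seed in comp else min(comp))
    scores = [_density(g.subgraph(c)) * len(c) for c in clusters]
    order_ix = sorted(range(len(clusters)), key=lambda i: (-scores[i], min(clusters[i])))
    return ModuleResult(
        clusters=[clusters[i] for i in order_ix],
        scores=[scores[i] for i in order_ix],
        seed_nodes=[seeds[i] for i in order_ix],
    )


def centralities(g: nx.Graph) -> pd.DataFrame:
    """Degree, normalized betweenness, and closeness per node.

    Betweenness uses fractional credit over tied geodesics and is
    normalized by (n-1)(n-2)/2 within each connected component of size n;
    closeness(v) = (n-1) / sum of hop distances within v's component.
    Singleton components get 0 for both.
    """
    deg = dict(g.degree)
    bet: dict[str, float] = {}
    clo: dict[str, float] = {}
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        n = sub.number_of_nodes()
        if n < 2:
            for v in comp:
                bet[v], clo[v] = 0.0, 0.0
            continue
        b = nx.betweenness_centrality(sub, normalized=(n > 2))
        c = nx.closeness_centrality(sub, wf_improved=False)
        bet.update(b)
        clo.update(c)
    nodes = sorted(g.nodes)
    return pd.DataFrame(
        {
            "degree": [deg[v] for v in nodes],
            "betweenness": [bet[v] for v in nodes],
            "closeness": [clo[v] for v in nodes],
        },
        index=pd.Index(nodes, name="node"),
    )


def rank_hubs(topo: pd.DataFrame, k: int = 5) -> list[str]:
    """Top-k nodes by the mean of their per-metric ranks (1 = best).

    Ties within a metric get average ranks; aggregate ties are broken by
    higher degree, then lexicographic id.
    """
    if k > len(topo):
        raise InputError(f"k={k} exceeds node count {len(topo)}")
    ranks = {
        m: rankdata(-topo[m].to_numpy(), method="average")
        for m in ("degree", "betweenness", "closeness")
    }
    aggregate = np.mean([ranks[m] for m in ranks], axis=0)
    df = topo.assign(aggregate_rank=aggregate)
    ordered = df.sort_values(
        ["aggregate_rank", "degree", "node"],
        ascending=[True, False, True],
        kind="mergesort",
    )
    return list(ordered.index[:k])


def topology_table(g: nx.Graph) -> pd.DataFrame:
    """Centralities plus the aggregate hub rank, ready for output."""
    topo = centralities(g)
    ranks = {
        m: rankdata(-topo[m].to_numpy(), method="average")
        for m in ("degree", "betweenness", "closeness")
    }
    topo["aggregate_rank"] = np.mean([ranks[m] for m in ranks], axis=0)
    return topo.sort_values(["aggregate_rank", "node"], kind="mergesort")
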