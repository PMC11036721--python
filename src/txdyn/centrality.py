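"""Twelve topological centrality measures and the top-k consensus hub rule.

The measures follow the cytoHubba conventions. For a simple undirected graph
G and node v with neighborhood N(v):

- Degree:      |N(v)|.
- MNC:         size of the largest connected component of G[N(v)].
- DMNC:        E / V^1.7 of that largest component (V nodes, E edges).
- MCC:         sum over maximal cliques C containing v of (|C| - 1)!;
               if no two neighbors of v are adjacent, MCC(v) = deg(v).
- Clustering:  2 e(N(v)) / (deg (deg - 1)); 0 for deg < 2.
- Betweenness: standard shortest-path betweenness (unnormalized).
- Stress:      number of shortest paths with v as an interior node.
- Closeness:   sum over reachable t != v of 1 / d(v, t) (harmonic, so
               disconnected graphs need no special-casing).
- EcCentricity: 1 / max distance to any reachable node.
- Radiality:   sum over t in v's component of (diam + 1 - d(v, t)) divided
               by (n_comp - 1), with diam the component diameter.
- BottleNeck:  number of sources s for which more than n_s / 4 units of
               shortest-path flow pass through v (one unit per target,
               split equally over tied predecessors; reduces to the
               shortest-path-tree descendant count when paths are unique).
- EPC:         edge-percolation connectivity — over R random realizations
               keeping each edge with probability equal to its combined
               score, the mean number of nodes connected to v.

Consensus hubs: a node's consensus count is the number of per-measure top-k
lists containing it; candidates are ranked by that count, then by mean rank
across measures, then lexicographically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd

MEASURES = (
    "MCC",
    "DMNC",
    "MNC",
    "Degree",
    "EPC",
    "BottleNeck",
    "EcCentricity",
    "Closeness",
    "Radiality",
    "Betweenness",
    "Stress",
    "ClusteringCoefficient",
)


@dataclass
class CentralityRanking:
    """Scores and the descending-order node ranking for one measure."""

    measure: str
    scores: dict[str, float]
    mc_standard_error: Optional[dict[str, float]] = None

    def top(self, k: int) -> list[str]:
        """Top-k nodes by descending score, ties broken lexicographically."""
        order = sorted(self.scores, key=lambda v: (-self.scores[v], v))
        return order[:k]

    def ranks(self) -> dict[str, int]:
        """1-based rank per node under the same ordering as top()."""
        order = sorted(self.scores, key=lambda v: (-self.scores[v], v))
        return {v: i + 1 for i, v in enumerate(order)}


def _largest_neighborhood_component(g: nx.Graph, v) -> nx.Graph:
    nbrs = list(g.neighbors(v))
    if not nbrs:
        return g.subgraph([])
    sub = g.subgraph(nbrs)
    comp = max(nx.connected_components(sub), key=lambda c: (len(c), sorted(c)))
    return sub.subgraph(comp)


def _mcc(g: nx.Graph) -> dict[str, float]:
    scores = {v: 0.0 for v in g.nodes}
    in_clique: dict[str, bool] = {v: False for v in g.nodes}
    for clique in nx.find_cliques(g):
        if len(clique) < 2:
            continue
        value = math.factorial(len(clique) - 1)
        for v in clique:
            if len(clique) >= 3:
                in_clique[v] = True
            scores[v] += value
    # nodes whose neighborhood is edgeless score their degree
    for v in g.nodes:
        if not in_clique[v]:
            scores[v] = float(g.degree(v))
    return scores


def _stress_and_betweenness(g: nx.Graph) -> tuple[dict[str, float], dict[str, float]]:
    """All-pairs BFS path counts; stress sums sigma_st(v), betweenness the ratios."""
    nodes = list(g.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    dist = np.full((n, n), np.inf)
    sigma = np.zeros((n, n))
    for s in nodes:
        si = idx[s]
        dist[si, si] = 0
        sigma[si, si] = 1
        lengths = dict(nx.single_source_shortest_path_length(g, s))
        order = sorted(lengths, key=lambda v: lengths[v])
        for t in order:
            if t == s:
                continue
            ti = idx[t]
            dist[si, ti] = lengths[t]
            sigma[si, ti] = sum(
                sigma[si, idx[u]] for u in g.neighbors(t) if lengths.get(u, -1) == lengths[t] - 1
            )
    stress = {}
    betw = {}
    for v in nodes:
        vi = idx[v]
        s_total = 0.0
        b_total = 0.0
        for a in range(n):
            if a == vi:
                continue
            for b in range(a + 1, n):
                if b == vi or not np.isfinite(dist[a, b]):
                    continue
                if dist[a, vi] + dist[vi, b] == dist[a, b]:
                    through = sigma[a, vi] * sigma[vi, b]
                    s_total += through
                    b_total += through / sigma[a, b]
        stress[v] = s_total
        betw[v] = b_total
    return stress, betw


def _bottleneck(g: nx.Graph) -> dict[str, float]:
    """Per source s, route one unit of flow from every target back to s along
    the shortest-path DAG, splitting equally over tied predecessors; v scores
    when more than n_s/4 units pass through it. With unique shortest paths
    this is the classic shortest-path-tree descendant count; the equal split
    keeps the measure symmetric on vertex-transitive graphs."""
    scores = {v: 0.0 for v in g.nodes}
    for s in sorted(g.nodes):
        lengths = dict(nx.single_source_shortest_path_length(g, s))
        preds = {
            t: [u for u in g.neighbors(t) if lengths.get(u, -1) == lengths[t] - 1]
            for t in lengths
            if t != s
        }
        n_s = len(lengths)
        arriving = {v: 0.0 for v in lengths}
        for t in sorted(lengths, key=lambda v: -lengths[v]):
            if t == s:
                continue
            share = (arriving[t] + 1.0) / len(preds[t])
            for u in preds[t]:
                arriving[u] += share
        for v in lengths:
            if v != s and arriving[v] > n_s / 4.0:
                scores[v] += 1.0
    return scores


def _epc(g: nx.Graph, rounds: int, rng: np.random.Generator) -> tuple[dict, dict]:
    nodes = list(g.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    edges = list(g.edges(data=True))
    probs = np.array([d.get("combined_score", 1.0) for _, _, d in edges])
    totals = np.zeros(len(nodes))
    squares = np.zeros(len(nodes))
    for _ in range(rounds):
        keep = rng.random(len(edges)) < probs
        h = nx.Graph()
        h.add_nodes_from(nodes)
        h.add_edges_from((a, b) for (a, b, _), k in zip(edges, keep) if k)
        counts = np.zeros(len(nodes))
        for comp in nx.connected_components(h):
            size = len(comp)
            for v in comp:
                counts[idx[v]] = size - 1  # nodes connected to v, excluding v
        totals += counts
        squares += counts**2
    mean = totals / rounds
    var = squares / rounds - mean**2
    se = np.sqrt(np.maximum(var, 0.0) / rounds)
    return (
        {v: float(mean[idx[v]]) for v in nodes},
        {v: float(se[idx[v]]) for v in nodes},
    )


def centrality(
    g: nx.Graph,
    measure: str,
    seed: Optional[int] = None,
    epc_rounds: int = 1000,
) -> CentralityRanking:
    """Compute one of the twelve measures on a simple undirected graph."""
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; choose from {MEASURES}")
    nodes = list(g.nodes)

    if measure == "Degree":
        return CentralityRanking(measure, {v: float(g.degree(v)) for v in nodes})

    if measure == "MNC":
        return CentralityRanking(
            measure,
            {v: float(_largest_neighborhood_component(g, v).number_of_nodes()) for v in nodes},
        )

    if measure == "DMNC":
        scores = {}
        for v in nodes:
            comp = _largest_neighborhood_component(g, v)
            nV, nE = comp.number_of_nodes(), comp.number_of_edges()
            scores[v] = nE / nV**1.7 if nV > 0 else 0.0
        return CentralityRanking(measure, scores)

    if measure == "MCC":
        return CentralityRanking(measure, _mcc(g))

    if measure == "ClusteringCoefficient":
        return CentralityRanking(measure, {v: float(c) for v, c in nx.clustering(g).items()})

    if measure == "Betweenness":
        _, betw = _stress_and_betweenness(g)
        return CentralityRanking(measure, betw)

    if measure == "Stress":
        stress, _ = _stress_and_betweenness(g)
        return CentralityRanking(measure, stress)

    if measure == "Closeness":
        scores = {}
        for v in nodes:
            lengths = nx.single_source_shortest_path_length(g, v)
            scores[v] = float(sum(1.0 / d for t, d in lengths.items() if t != v))
        return CentralityRanking(measure, scores)

    if measure == "EcCentricity":
        scores = {}
        for v in nodes:
            lengths = nx.single_source_shortest_path_length(g, v)
            ecc = max(lengths.values())
            scores[v] = 1.0 / ecc if ecc > 0 else 0.0
        return CentralityRanking(measure, scores)

    if measure == "Radiality":
        scores = {}
        for comp in nx.connected_components(g):
            sub = g.subgraph(comp)
            n_comp = len(comp)
            if n_comp == 1:
                scores[next(iter(comp))] = 0.0
                continue
            diam = nx.diameter(sub)
            for v in comp:
                lengths = nx.single_source_shortest_path_length(sub, v)
                scores[v] = float(
                    sum(diam + 1 - d for t, d in lengths.items() if t != v) / (n_comp - 1)
                )
        return CentralityRanking(measure, scores)

    if measure == "BottleNeck":
        return CentralityRanking(measure, _bottleneck(g))

    # EPC
    if seed is None:
        raise ValueError("EPC is Monte-Carlo; a seed is required")
    rng = np.random.default_rng(seed)
    mean, se = _epc(g, epc_rounds, rng)
    return CentralityRanking(measure, mean, mc_standard_error=se)


def all_centralities(
    g: nx.Graph, seed: Optional[int] = None, epc_rounds: int = 1000
) -> dict[str, CentralityRanking]:
    """All twelve measures; seed feeds the EPC percolation."""
    return {m: centrality(g, m, seed=seed, epc_rounds=epc_rounds) for m in MEASURES}


def consensus_hubs(
    rankings: dict[str, CentralityRanking], k: int = 5
) -> tuple[list[str], pd.DataFrame]:
    """Consensus hub selection across the twelve per-measure top-k lists.

    Returns (hub list of length k, membership matrix). The matrix has one
    row per node with 0/1 membership per measure, the consensus count, the
    mean rank across measures, and whether the node lies in the strict
    12-way intersection of top-k lists.
    """
    missing = [m for m in MEASURES if m not in rankings]
    if missing:
        raise ValueError(f"missing measures: {missing}")
    node_sets = [set(rankings[m].scores) for m in MEASURES]
    nodes = node_sets[0]
    if any(s != nodes for s in node_sets[1:]):
        raise ValueError("rankings were not computed on the same node set")

    tops = {m: rankings[m].top(k) for m in MEASURES}
    ranks = {m: rankings[m].ranks() for m in MEASURES}
    rows = []
    for v in sorted(nodes):
        membership = [1 if v in tops[m] else 0 for m in MEASURES]
        mean_rank = float(np.mean([ranks[m][v] for m in MEASURES]))
        rows.append([v, *membership, sum(membership), mean_rank])
    matrix = pd.DataFrame(
        rows, columns=["node", *MEASURES, "consensus_count", "mean_rank"]
    ).set_index("node")
    strict = set.intersection(*(set(tops[m]) for m in MEASURES))
    matrix["in_strict_intersection"] = [v in strict for v in matrix.index]

    ordered = sorted(
        matrix.index,
        key=lambda v: (-matrix.at[v, "consensus_count"], matrix.at[v, "mean_rank"], v),
    )
    return ordered[:k], matrix
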