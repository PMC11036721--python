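"""Interaction-graph construction and MCODE-style dense-module extraction.

The graph is built from a STRING-like weighted edge list, keeping edges with
combined score >= a confidence threshold (default 0.400) and hiding nodes
left without any edge. Module extraction follows the MCODE scheme: each
vertex is weighted by the density of the highest k-core of its closed
neighborhood scaled by that core number; modules grow greedily from the
highest-weighted unvisited seed, admitting neighbors whose weight is within
(1 - node_score_cutoff) of the seed's; post-processing optionally shaves
degree-1 members (haircut) or pulls in dense fringe neighbors (fluff), and
modules that do not contain a 2-core are discarded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import pandas as pd


def build_graph(edges: pd.DataFrame, min_score: float = 0.400) -> nx.Graph:
    """Score-filtered simple graph from an edge table.

    *edges* needs columns (node1, node2, combined_score) — by name if
    present, else the first three columns. Scores on the STRING 0-999 scale
    are auto-detected (any score > 1) and rescaled to 0-1. The threshold is
    inclusive (score >= min_score kept); nodes without a surviving edge are
    dropped.
    """
    if edges.shape[1] < 3:
        raise ValueError("edge table needs 3 columns: node1, node2, combined_score")
    cols = list(edges.columns)
    if {"node1", "node2", "combined_score"} <= set(cols):
        table = edges[["node1", "node2", "combined_score"]].copy()
    else:
        table = edges.iloc[:, :3].copy()
        table.columns = ["node1", "node2", "combined_score"]
    scores = pd.to_numeric(table["combined_score"], errors="coerce")
    bad = scores.isna()
    if bad.any():
        raise ValueError(f"malformed score at row(s) {list(table.index[bad][:5])}")
    if (scores > 1).any():  # STRING integer dialect, 0-999
        scores = scores / 1000.0
    if (scores < 0).any() or (scores > 1).any():
        raise ValueError("scores must lie in [0, 1] (or the 0-999 STRING dialect)")

    g = nx.Graph()
    for (a, b), s in zip(zip(table["node1"], table["node2"]), scores):
        if a == b:
            continue  # no self-loops
        if s >= min_score:
            prev = g.get_edge_data(a, b)
            if prev is None or s > prev["combined_score"]:
                g.add_edge(str(a), str(b), combined_score=float(s))
    if g.number_of_edges() == 0:
        warnings.warn("no edges pass the score threshold; graph is empty", stacklevel=2)
    return g


def _density(n: int, e: int) -> float:
    return 0.0 if n < 2 else 2.0 * e / (n * (n - 1))


def vertex_weights(g: nx.Graph) -> dict[str, float]:
    """MCODE vertex weighting: core number x density of the highest k-core
    of the node's closed neighborhood."""
    weights: dict[str, float] = {}
    for v in g.nodes:
        closed = list(g.neighbors(v)) + [v]
        sub = g.subgraph(closed)
        if sub.number_of_edges() == 0:
            weights[v] = 0.0
            continue
        core = nx.core_number(sub)
        kmax = max(core.values())
        top = [u for u, c in core.items() if c == kmax]
        core_sub = sub.subgraph(top)
        weights[v] = kmax * _density(core_sub.number_of_nodes(), core_sub.number_of_edges())
    return weights


@dataclass
class ModuleResult:
    """One extracted dense module."""

    nodes: frozenset[str]
    seed: str
    score: float  # MCODE module score: density x size
    n_nodes: int
    n_edges: int

    def subgraph(self, g: nx.Graph) -> nx.Graph:
        return g.subgraph(self.nodes)


def _has_k_core(sub: nx.Graph, k: int) -> bool:
    return len(nx.k_core(sub, k)) > 0


def extract_modules(
    g: nx.Graph,
    node_score_cutoff: float = 0.2,
    k_core_min: int = 2,
    haircut: bool = True,
    fluff: bool = False,
    fluff_density: float = 0.1,
) -> list[ModuleResult]:
    """Greedy seed-and-expand dense modules over MCODE vertex weights.

    Seeds are taken in descending weight order (ties lexicographic);
    expansion admits unvisited neighbors with weight >= seed_weight *
    (1 - node_score_cutoff). Haircut removes module nodes of within-module
    degree 1; fluff (off by default) adds fringe neighbors whose closed-
    neighborhood density exceeds fluff_density. Modules without a
    k_core_min-core are discarded; every node belongs to at most one module.
    Results are sorted by descending score (density x node count).
    """
    weights = vertex_weights(g)
    visited: set[str] = set()
    modules: list[ModuleResult] = []

    for seed in sorted(weights, key=lambda v: (-weights[v], v)):
        if seed in visited:
            continue
        threshold = weights[seed] * (1.0 - node_score_cutoff)
        members = {seed}
        frontier = [seed]
        visited.add(seed)
        while frontier:
            v = frontier.pop()
            for u in g.neighbors(v):
                if u in visited or u in members:
                    continue
                if weights[u] >= threshold:
                    members.add(u)
                    visited.add(u)
                    frontier.append(u)
        sub = g.subgraph(members)
        if haircut:
            pruned = set(members)
            while True:
                sub = g.subgraph(pruned)
                leaves = [v for v in pruned if sub.degree(v) <= 1 and len(pruned) > 1]
                if not leaves:
                    break
                pruned -= set(leaves)
            members = pruned
            sub = g.subgraph(members)
        if fluff:
            extra = set()
            for v in list(members):
                for u in g.neighbors(v):
                    if u in members or u in extra:
                        continue
                    closed = list(g.neighbors(u)) + [u]
                    csub = g.subgraph(closed)
                    if _density(csub.number_of_nodes(), csub.number_of_edges()) > fluff_density:
                        extra.add(u)
                        visited.add(u)  # keep modules node-disjoint
            members = members | extra
            sub = g.subgraph(members)
        if len(members) < 2 or not _has_k_core(g.subgraph(members), k_core_min):
            continue
        sub = g.subgraph(members)
        n, e = sub.number_of_nodes(), sub.number_of_edges()
        modules.append(
            ModuleResult(
                nodes=frozenset(members),
                seed=seed,
                score=_density(n, e) * n,
                n_nodes=n,
                n_edges=e,
            )
        )
    modules.sort(key=lambda m: (-m.score, sorted(m.nodes)[0]))
    return modules


def preliminary_hubs(module: ModuleResult, g: nx.Graph, n: int = 5) -> list[str]:
    """Top-n module genes by within-module degree.

    Ties break by total-graph degree, then lexicographically. If the module
    has fewer than n members, all are returned with a warning.
    """
    if not module.nodes:
        raise ValueError("empty module")
    sub = g.subgraph(module.nodes)
    ranked = sorted(module.nodes, key=lambda v: (-sub.degree(v), -g.degree(v), v))
    if len(ranked) < n:
        warnings.warn(
            f"module has only {len(ranked)} nodes; returning all", stacklevel=2
        )
    return ranked[:n]
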