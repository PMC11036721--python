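"""Independent brute-force oracles for small graphs and small universes.

Everything here is written from first principles on adjacency dicts and
itertools enumeration — deliberately sharing no code path with the package —
so centrality scores, module densities and hypergeometric tails can be
cross-checked exactly on instances small enough to enumerate.
"""

from __future__ import annotations

import itertools
import math
from collections import deque


def adjacency(edges, nodes=None):
    adj: dict[str, set[str]] = {n: set() for n in (nodes or [])}
    for a, b in edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    return adj


def bfs_distances(adj, source):
    dist = {source: 0}
    queue = deque([source])
    while queue:
        v = queue.popleft()
        for u in sorted(adj[v]):
            if u not in dist:
                dist[u] = dist[v] + 1
                queue.append(u)
    return dist


def all_shortest_paths(adj, s, t):
    """Enumerate every shortest s-t path by backtracking over BFS distances."""
    dist = bfs_distances(adj, s)
    if t not in dist:
        return []
    paths = []

    def fwd(node, path):
        if node == t:
            paths.append(path)
            return
        for u in sorted(adj[node]):
            if dist.get(u, 10**9) == dist[node] + 1 and dist[u] <= dist[t]:
                fwd(u, path + [u])

    fwd(s, [s])
    return paths


def components(adj, subset=None):
    nodes = set(adj) if subset is None else set(subset)
    seen: set[str] = set()
    comps = []
    for start in sorted(nodes):
        if start in seen:
            continue
        comp = {start}
        queue = deque([start])
        seen.add(start)
        while queue:
            v = queue.popleft()
            for u in adj[v]:
                if u in nodes and u not in seen:
                    seen.add(u)
                    comp.add(u)
                    queue.append(u)
        comps.append(comp)
    return comps


def maximal_cliques(adj):
    """All maximal cliques of a graph with <= ~15 nodes by subset enumeration."""
    nodes = sorted(adj)
    cliques = []
    for r in range(1, len(nodes) + 1):
        for subset in itertools.combinations(nodes, r):
            if all(b in adj[a] for a, b in itertools.combinations(subset, 2)):
                cliques.append(set(subset))
    return [
        c
        for c in cliques
        if not any(c < other for other in cliques)
    ]


def oracle_degree(adj, v):
    return float(len(adj[v]))


def oracle_mnc_component(adj, v):
    nbrs = adj[v]
    if not nbrs:
        return set()
    sub = {n: adj[n] & nbrs for n in nbrs}
    comps = components(sub)
    return max(comps, key=lambda c: (len(c), sorted(c)))


def oracle_mnc(adj, v):
    return float(len(oracle_mnc_component(adj, v)))


def oracle_dmnc(adj, v):
    comp = oracle_mnc_component(adj, v)
    if not comp:
        return 0.0
    e = sum(1 for a, b in itertools.combinations(sorted(comp), 2) if b in adj[a])
    return e / len(comp) ** 1.7


def oracle_mcc(adj, v):
    cliques = [c for c in maximal_cliques(adj) if v in c and len(c) >= 2]
    has_triangle = any(len(c) >= 3 for c in cliques)
    if not has_triangle:
        return float(len(adj[v]))
    return float(sum(math.factorial(len(c) - 1) for c in cliques))


def oracle_clustering(adj, v):
    deg = len(adj[v])
    if deg < 2:
        return 0.0
    e = sum(1 for a, b in itertools.combinations(sorted(adj[v]), 2) if b in adj[a])
    return 2.0 * e / (deg * (deg - 1))


def oracle_betweenness_stress(adj):
    nodes = sorted(adj)
    betw = {v: 0.0 for v in nodes}
    stress = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = all_shortest_paths(adj, s, t)
        if not paths:
            continue
        sigma = len(paths)
        interior: dict[str, int] = {}
        for path in paths:
            for v in path[1:-1]:
                interior[v] = interior.get(v, 0) + 1
        for v, count in interior.items():
            stress[v] += count
            betw[v] += count / sigma
    return betw, stress


def oracle_closeness(adj, v):
    dist = bfs_distances(adj, v)
    return float(sum(1.0 / d for t, d in dist.items() if t != v))


def oracle_eccentricity(adj, v):
    dist = bfs_distances(adj, v)
    ecc = max(dist.values())
    return 1.0 / ecc if ecc > 0 else 0.0


def oracle_radiality(adj, v):
    comp = next(c for c in components(adj) if v in c)
    if len(comp) == 1:
        return 0.0
    diam = max(
        max(bfs_distances(adj, u)[w] for w in comp) for u in comp
    )
    dist = bfs_distances(adj, v)
    return sum(diam + 1 - dist[t] for t in comp if t != v) / (len(comp) - 1)


def oracle_bottleneck(adj):
    """Fractional back-flow over the shortest-path DAG, recursively per target."""
    nodes = sorted(adj)
    scores = {v: 0.0 for v in nodes}
    for s in nodes:
        dist = bfs_distances(adj, s)
        n_s = len(dist)
        routed = {v: 0.0 for v in dist}

        def push(node, frac):
            preds = [u for u in adj[node] if dist.get(u, -1) == dist[node] - 1]
            for u in preds:
                if u != s:
                    routed[u] += frac / len(preds)
                    push(u, frac / len(preds))

        for t in dist:
            if t != s:
                push(t, 1.0)
        for v in dist:
            if v != s and routed[v] > n_s / 4.0:
                scores[v] += 1.0
    return scores


def oracle_hypergeom_upper(N, K, n, k):
    """P(overlap >= k) by exhaustive enumeration of n-subsets of an N-universe."""
    universe = list(range(N))
    hits = total = 0
    for subset in itertools.combinations(universe, n):
        total += 1
        if sum(1 for g in subset if g < K) >= k:
            hits += 1
    return hits / total
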