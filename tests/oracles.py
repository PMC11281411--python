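"""Independent brute-force oracles used by the test suite.

These deliberately avoid the algorithms used by the package (and by
networkx where the package delegates): betweenness/closeness come from
exhaustive simple-path enumeration, the BH adjustment from the literal
step-up definition, and Spearman null rates from full permutation
enumeration at small n.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np


def bh_stepup(pvals):
    """Benjamini-Hochberg adjusted p-values by the literal step-up rule:
    q_(i) = min_{j >= i} p_(j) * m / j, clipped at 1."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.empty(m)
    running = np.inf
    for rank in range(m - 1, -1, -1):
        running = min(running, p[order[rank]] * m / (rank + 1))
        q_sorted[rank] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def _all_simple_paths(adj, s, t):
    """All simple s-t paths by depth-first enumeration."""
    paths = []
    stack = [(s, [s])]
    while stack:
        node, path = stack.pop()
        if node == t:
            paths.append(path)
            continue
        for nbr in adj[node]:
            if nbr not in path:
                stack.append((nbr, path + [nbr]))
    return paths


def brute_path_centralities(G: nx.Graph):
    """Degree, normalized betweenness, Wasserman-Faust closeness and local
    clustering from exhaustive path enumeration on a small graph."""
    nodes = list(G.nodes)
    n = len(nodes)
    adj = {v: set(G.neighbors(v)) for v in nodes}

    dist = {v: {v: 0} for v in nodes}
    betweenness = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = _all_simple_paths(adj, s, t)
        if not paths:
            continue
        d = min(len(p) - 1 for p in paths)
        shortest = [p for p in paths if len(p) - 1 == d]
        dist[s][t] = dist[t][s] = d
        sigma = len(shortest)
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in shortest if v in p)
            betweenness[v] += through / sigma
    scale = (n - 1) * (n - 2) / 2.0
    if scale > 0:
        betweenness = {v: b / scale for v, b in betweenness.items()}

    closeness = {}
    for v in nodes:
        reach = [u for u in nodes if u != v and u in dist[v]]
        if not reach:
            closeness[v] = 0.0
            continue
        total = sum(dist[v][u] for u in reach)
        r = len(reach)
        closeness[v] = (r / total) * (r / (n - 1)) if total > 0 else 0.0

    clustering = {}
    for v in nodes:
        nbrs = list(adj[v])
        k = len(nbrs)
        if k < 2:
            clustering[v] = 0.0
            continue
        links = sum(1 for a, b in itertools.combinations(nbrs, 2) if b in adj[a])
        clustering[v] = 2.0 * links / (k * (k - 1))

    degree = {v: len(adj[v]) for v in nodes}
    return degree, betweenness, closeness, clustering


def exact_spearman_edge_rate(n: int, r_min: float, p_max: float) -> float:
    """Exact null probability of the co-occurrence edge rule for untied
    data at sample size n, by enumerating all n! rank permutations."""
    from scipy import stats

    base = np.arange(1, n + 1)
    hits = 0
    total = 0
    for perm in itertools.permutations(base):
        d2 = float(((base - np.asarray(perm)) ** 2).sum())
        r = 1.0 - 6.0 * d2 / (n * (n * n - 1))
        total += 1
        if abs(r) <= r_min:
            continue
        if abs(r) >= 1.0:
            hits += 1
            continue
        t = abs(r) * np.sqrt((n - 2) / (1.0 - r * r))
        if 2.0 * stats.t.sf(t, n - 2) < p_max:
            hits += 1
    return hits / total


def make_net(edges, default_layer="virome"):
    """Build a toy co-occurrence network with valid edge/node attributes.

    ``edges`` is an iterable of (u, v) or (u, v, r) tuples.
    """
    from momnet.tables import LAYER_PREFIX

    net = nx.Graph()
    for edge in edges:
        u, v, r = (*edge, 1.0) if len(edge) == 2 else edge
        net.add_edge(u, v, r=float(r), p=1e-6, q=1e-6,
                     sign=1 if r > 0 else -1, absr=abs(float(r)))
    prefixes = {p: layer for layer, p in LAYER_PREFIX.items()}
    for node in net.nodes:
        layer = default_layer
        for prefix, lname in prefixes.items():
            if str(node).startswith(prefix):
                layer = lname
        net.nodes[node]["layer"] = layer
    return net
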