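"""Independent brute-force oracles used to cross-check the implementations."""

from __future__ import annotations

import itertools

import numpy as np


def brute_force_betweenness(network, alpha=0.5, rtol=1e-9):
    """Betweenness by exhaustive enumeration of all simple paths.

    For every ordered pair (s, t) all simple paths are enumerated, their
    costs sum((1/w)**alpha) computed, and minimal-cost paths (within
    relative tolerance) counted.  Intermediate nodes of minimal paths
    accumulate fractional counts.  Only feasible for small graphs.
    """
    nodes = list(network.nodes)
    adj: dict[str, dict[str, float]] = {v: {} for v in nodes}
    for u, v, d in network.graph.edges(data=True):
        cost = (1.0 / d["weight"]) ** alpha
        adj[u][v] = cost
        if not network.directed:
            adj[v][u] = cost

    def simple_paths(s, t):
        stack = [(s, [s], 0.0)]
        while stack:
            node, path, cost = stack.pop()
            if node == t:
                yield path, cost
                continue
            for nxt, c in adj[node].items():
                if nxt not in path:
                    stack.append((nxt, path + [nxt], cost + c))

    bc = dict.fromkeys(nodes, 0.0)
    for s, t in itertools.permutations(nodes, 2):
        paths = list(simple_paths(s, t))
        if not paths:
            continue
        best = min(c for _, c in paths)
        tol = rtol * max(1.0, abs(best))
        minimal = [p for p, c in paths if c <= best + tol]
        for path in minimal:
            for v in path[1:-1]:
                bc[v] += 1.0 / len(minimal)
    return bc


def kruskal_wallis_h(groups):
    """Tie-corrected Kruskal-Wallis H via the textbook rank formula."""
    from scipy.stats import rankdata

    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    ranks = rankdata(pooled)
    n = len(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + len(g)]
        start += len(g)
        h += r.sum() ** 2 / len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    return h / correction
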