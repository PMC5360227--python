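"""Individual and global network metrics.

Binary measures (degree, density, degree centralization) ignore weights.
Weighted measures follow the generalized convention in which a tuning
parameter ``alpha`` in [0, 1] balances the number of ties against their
strength: ``alpha = 0`` counts ties only, ``alpha = 1`` uses pure weight
sums, and intermediate values interpolate geometrically.  Shortest-path
costs for weighted betweenness are ``(1 / w)**alpha`` per edge, so heavy
edges are short.  Clustering is computed on the symmetrised network.
"""

from __future__ import annotations

import heapq
import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import SocialNetwork, symmetrise

__all__ = [
    "GlobalMetrics",
    "binary_degrees",
    "strengths",
    "generalized_degree",
    "weighted_betweenness",
    "weighted_local_clustering",
    "density",
    "degree_centralization",
    "mean_clustering",
    "global_metrics",
    "node_metrics",
    "TRIPLET_VALUE_FUNCS",
]

#: relative tolerance for detecting equal-cost shortest paths
PATH_TIE_RTOL = 1e-10

TRIPLET_VALUE_FUNCS = {
    "arithmetic_mean": lambda a, b: (a + b) / 2.0,
    "geometric_mean": lambda a, b: math.sqrt(a * b),
    "max": max,
    "min": min,
}


@dataclass(frozen=True)
class GlobalMetrics:
    """Whole-network summary: density, degree centralization, mean clustering."""

    density: float
    degree_centralization: float
    mean_clustering: float  # NaN when no node has >= 2 neighbours

    def as_dict(self) -> dict[str, float]:
        return {
            "density": self.density,
            "degree_centralization": self.degree_centralization,
            "mean_clustering": self.mean_clustering,
        }


# ---------------------------------------------------------------------------
# degrees and strengths
# ---------------------------------------------------------------------------

def binary_degrees(network: SocialNetwork) -> pd.DataFrame:
    """Per-node binary degrees: total (symmetrised), in and out (directed).

    For an undirected network in- and out-degree both equal the total
    degree.
    """
    sym = symmetrise(network)
    rows = {}
    for v in network.nodes:
        total = sym.graph.degree(v)
        if network.directed:
            in_d = network.graph.in_degree(v)
            out_d = network.graph.out_degree(v)
        else:
            in_d = out_d = total
        rows[v] = {"degree": total, "in_degree": in_d, "out_degree": out_d}
    return pd.DataFrame.from_dict(rows, orient="index").reindex(network.nodes)


def strengths(network: SocialNetwork) -> pd.DataFrame:
    """Per-node in- and out-strength (sums of incident edge weights)."""
    rows = {}
    for v in network.nodes:
        if network.directed:
            out_s = sum(d["weight"] for _, _, d in network.graph.out_edges(v, data=True))
            in_s = sum(d["weight"] for _, _, d in network.graph.in_edges(v, data=True))
        else:
            out_s = in_s = sum(d["weight"] for _, _, d in network.graph.edges(v, data=True))
        rows[v] = {"in_strength": float(in_s), "out_strength": float(out_s)}
    return pd.DataFrame.from_dict(rows, orient="index").reindex(network.nodes)


def generalized_degree(
    network: SocialNetwork,
    alpha: float,
    direction: str = "all",
) -> pd.Series:
    """Tuned degree ``k**(1 - alpha) * s**alpha`` per node.

    ``direction`` selects which ties are counted: ``"in"``, ``"out"`` or
    ``"all"`` (symmetrised ties; strength is then in + out).  Nodes with
    no ties score 0 for every alpha.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    if direction not in {"in", "out", "all"}:
        raise ValueError(f"direction must be in/out/all, got {direction!r}")
    deg = binary_degrees(network)
    st = strengths(network)
    if direction == "all":
        k = deg["degree"].to_numpy(dtype=float)
        s = (st["in_strength"] + st["out_strength"]).to_numpy(dtype=float)
    else:
        k = deg[f"{direction}_degree"].to_numpy(dtype=float)
        s = st[f"{direction}_strength"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        val = np.where(k > 0, k ** (1.0 - alpha) * s**alpha, 0.0)
    return pd.Series(val, index=network.nodes, name=f"generalized_degree[{direction}]")


# ---------------------------------------------------------------------------
# weighted betweenness (Brandes with tolerance-based tie detection)
# ---------------------------------------------------------------------------

def _edge_costs(network: SocialNetwork, alpha: float) -> dict[str, list[tuple[str, float]]]:
    """Adjacency with shortest-path costs (1/w)**alpha; undirected edges both ways."""
    adj: dict[str, list[tuple[str, float]]] = {v: [] for v in network.nodes}
    for u, v, d in network.graph.edges(data=True):
        w = float(d["weight"])
        if not w > 0:
            raise ValueError(f"non-positive edge weight on ({u}, {v}): {w}")
        cost = (1.0 / w) ** alpha
        adj[u].append((v, cost))
        if not network.directed:
            adj[v].append((u, cost))
    return adj


def _is_tie(a: float, b: float, rtol: float = PATH_TIE_RTOL) -> bool:
    return abs(a - b) <= rtol * max(1.0, abs(a), abs(b))


def weighted_betweenness(
    network: SocialNetwork,
    alpha: float = 0.5,
    rtol: float = PATH_TIE_RTOL,
) -> pd.Series:
    """Raw (unnormalized) shortest-path betweenness on the weighted network.

    Every ordered pair (s, t), s != t, contributes ``sigma_st(v)/sigma_st``
    to intermediate node v, where sigma counts minimal-cost paths under the
    cost ``(1/w)**alpha``.  Path-cost ties are detected with relative
    tolerance ``rtol`` because real-valued costs make exact equality
    fragile.  Unreachable pairs contribute nothing.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    adj = _edge_costs(network, alpha)
    bc = dict.fromkeys(network.nodes, 0.0)
    counter = itertools.count()
    for s in network.nodes:
        # Dijkstra phase, tracking path counts and predecessor lists
        S: list[str] = []
        P: dict[str, list[str]] = {v: [] for v in adj}
        sigma = dict.fromkeys(adj, 0.0)
        sigma[s] = 1.0
        dist: dict[str, float] = {}
        seen: dict[str, float] = {s: 0.0}
        heap: list[tuple[float, int, str | None, str]] = [(0.0, next(counter), None, s)]
        while heap:
            d, _, pred, v = heapq.heappop(heap)
            if v in dist:
                continue
            if pred is not None:
                sigma[v] += sigma[pred]
            dist[v] = d
            S.append(v)
            for w, cost in adj[v]:
                vw_dist = d + cost
                if w in dist:
                    continue
                if w not in seen or (vw_dist < seen[w] and not _is_tie(vw_dist, seen[w], rtol)):
                    seen[w] = vw_dist
                    heapq.heappush(heap, (vw_dist, next(counter), v, w))
                    sigma[w] = 0.0  # drop contributions routed via longer paths
                    P[w] = [v]
                elif _is_tie(vw_dist, seen[w], rtol):
                    sigma[w] += sigma[v]
                    P[w].append(v)
        # accumulation phase
        delta = dict.fromkeys(adj, 0.0)
        for w in reversed(S):
            for v in P[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    return pd.Series(bc, name="betweenness").reindex(network.nodes)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def weighted_local_clustering(
    network: SocialNetwork,
    triplet_value: str = "arithmetic_mean",
) -> pd.Series:
    """Weighted local clustering on the symmetrised network.

    For node i, every unordered pair of neighbours (j, k) is a triplet
    centred on i with value f(w(i,j), w(i,k)); the coefficient is the
    value-weighted fraction of those triplets that are closed by a j-k
    edge.  Nodes with fewer than two neighbours get NaN (undefined).
    """
    try:
        f = TRIPLET_VALUE_FUNCS[triplet_value]
    except KeyError:
        raise ValueError(
            f"unknown triplet_value {triplet_value!r}; "
            f"choose from {sorted(TRIPLET_VALUE_FUNCS)}"
        ) from None
    sym = symmetrise(network)
    out = _local_clustering_values(sym.graph, f)
    return pd.Series(out, name="clustering").reindex(network.nodes)


def _local_clustering_values(g, f) -> dict[str, float]:
    """Local clustering per node of an undirected weighted graph."""
    adj = {v: dict(nbrs) for v, nbrs in g.adjacency()}
    out = {}
    for i, nbrs in adj.items():
        if len(nbrs) < 2:
            out[i] = math.nan
            continue
        closed = total = 0.0
        items = [(j, d["weight"]) for j, d in nbrs.items()]
        for a, (j, wj) in enumerate(items):
            adj_j = adj[j]
            for k, wk in items[a + 1:]:
                val = f(wj, wk)
                total += val
                if k in adj_j:
                    closed += val
        out[i] = closed / total if total > 0 else math.nan
    return out


# ---------------------------------------------------------------------------
# global metrics
# ---------------------------------------------------------------------------

def density(network: SocialNetwork) -> float:
    """Fraction of possible ties present.

    Directed networks use n(n-1) possible ordered ties; undirected ones
    n(n-1)/2.
    """
    n = network.n_nodes
    if n < 2:
        raise ValueError("density requires at least 2 nodes")
    possible = n * (n - 1) if network.directed else n * (n - 1) / 2
    return network.n_edges / possible


def degree_centralization(network: SocialNetwork) -> float:
    """Freeman degree centralization on the symmetrised binary network.

    ``sum_i (d_max - d_i) / ((n - 1)(n - 2))``; 1 for a star, 0 when all
    degrees are equal.
    """
    n = network.n_nodes
    if n < 3:
        raise ValueError("degree centralization requires at least 3 nodes")
    sym = symmetrise(network)
    degs = [sym.graph.degree(v) for v in sym.graph.nodes]
    d_max = max(degs)
    return sum(d_max - d for d in degs) / ((n - 1) * (n - 2))


def mean_clustering(
    network: SocialNetwork,
    triplet_value: str = "arithmetic_mean",
) -> float:
    """Mean of defined local clustering values (NaN if none are defined)."""
    local = weighted_local_clustering(network, triplet_value)
    defined = local.dropna()
    if defined.empty:
        return math.nan
    return float(defined.mean())


def global_metrics(
    network: SocialNetwork,
    triplet_value: str = "arithmetic_mean",
) -> GlobalMetrics:
    # symmetrise once; centralization and clustering both need it
    n = network.n_nodes
    if n < 3:
        raise ValueError("global metrics require at least 3 nodes")
    sym = symmetrise(network)
    degs = [sym.graph.degree(v) for v in sym.graph.nodes]
    d_max = max(degs) if degs else 0
    centralization = sum(d_max - d for d in degs) / ((n - 1) * (n - 2))
    local = _local_clustering_values(
        sym.graph, TRIPLET_VALUE_FUNCS[triplet_value]
    )
    defined = [v for v in local.values() if not math.isnan(v)]
    return GlobalMetrics(
        density=density(network),
        degree_centralization=centralization,
        mean_clustering=float(np.mean(defined)) if defined else math.nan,
    )


def node_metrics(
    network: SocialNetwork,
    alpha: float = 0.5,
    triplet_value: str = "arithmetic_mean",
) -> pd.DataFrame:
    """Per-individual metric table.

    Columns: degree, in_degree, out_degree (binary), in_strength,
    out_strength, betweenness (weighted, ``alpha``) and clustering
    (weighted, symmetrised).
    """
    table = binary_degrees(network).join(strengths(network))
    table["betweenness"] = weighted_betweenness(network, alpha=alpha)
    table["clustering"] = weighted_local_clustering(network, triplet_value)
    table.index.name = "id"
    return table
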