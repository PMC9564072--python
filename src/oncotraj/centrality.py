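"""The 12 node-centrality measures used for PPI hub mining.

Degree, MCC, DMNC, MNC, EPC, BottleNeck, EcCentricity, Closeness, Radiality,
Betweenness, Stress and ClusteringCoefficient, following the cytoHubba
conventions on an unweighted simple graph.  Distance-based measures are
computed per connected component; unreachable vertex pairs contribute 0.

Conventions fixed here (the original definitions leave them open):

* MCC counts maximal cliques of size >= 2 (an isolated node scores 0).
* DMNC uses epsilon = 1.7 on the largest connected component of the open
  neighbourhood.
* EPC keeps each edge independently with probability 0.5 and averages, over
  seeded Monte-Carlo replicates, the number of other vertices reachable.
* BottleNeck trees are BFS trees with neighbours explored in sorted node
  order; v scores a point for root s (v != s) when more than |tree|/4 nodes
  hang below v.
* EcCentricity is the reciprocal eccentricity within the component
  (isolated nodes score 0); Closeness is harmonic (sum of 1/d).
"""

from __future__ import annotations

from collections import deque

import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["compute_centralities", "select_hubs", "MEASURES"]

MEASURES = [
    "Degree",
    "MCC",
    "DMNC",
    "MNC",
    "EPC",
    "BottleNeck",
    "EcCentricity",
    "Closeness",
    "Radiality",
    "Betweenness",
    "Stress",
    "ClusteringCoefficient",
]

_DMNC_EPS = 1.7


def _bfs_counts(adj_lists, n, source):
    """Distances and shortest-path counts from one source."""
    dist = np.full(n, -1, dtype=np.int64)
    sigma = np.zeros(n, dtype=np.float64)
    dist[source] = 0
    sigma[source] = 1.0
    q = deque([source])
    while q:
        u = q.popleft()
        for w in adj_lists[u]:
            if dist[w] < 0:
                dist[w] = dist[u] + 1
                q.append(w)
            if dist[w] == dist[u] + 1:
                sigma[w] += sigma[u]
    return dist, sigma


def _mcc(graph: nx.Graph, nodes) -> dict:
    import math

    out = {v: 0.0 for v in nodes}
    for clique in nx.find_cliques(graph):
        if len(clique) < 2:
            continue
        score = math.factorial(len(clique) - 1)
        for v in clique:
            out[v] += score
    return out


def _neighborhood_component(graph: nx.Graph, v):
    """Maximum component of the open neighbourhood; size ties go to the
    denser component (most edges), then to the smallest vertex labels."""
    nbrs = list(graph.neighbors(v))
    if not nbrs:
        return None
    sub = graph.subgraph(nbrs)
    comp = min(
        nx.connected_components(sub),
        key=lambda c: (
            -len(c),
            -sub.subgraph(c).number_of_edges(),
            tuple(sorted(map(str, c))),
        ),
    )
    return sub.subgraph(comp)


def _epc(graph: nx.Graph, nodes, n_reps: int, seed: int) -> dict:
    """Mean count of other vertices reachable under 0.5 edge percolation.

    Small graphs (n <= 32) run all replicates as one batched boolean-closure
    computation; larger graphs fall back to per-replicate sparse connected
    components.
    """
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    edges = np.array([(idx[u], idx[v]) for u, v in graph.edges], dtype=np.int64)
    if len(edges) == 0:
        return {v: 0.0 for v in nodes}
    rng = np.random.default_rng(seed)
    if n <= 32:
        keep = rng.random((n_reps, len(edges))) < 0.5
        reach = np.broadcast_to(np.eye(n, dtype=np.float32), (n_reps, n, n)).copy()
        reach[:, edges[:, 0], edges[:, 1]] = keep
        reach[:, edges[:, 1], edges[:, 0]] = keep
        for _ in range(max(1, int(np.ceil(np.log2(n))))):
            reach = (reach @ reach > 0).astype(np.float32)
        totals = reach.sum(axis=2).sum(axis=0) - n_reps
    else:
        from scipy.sparse import coo_matrix
        from scipy.sparse.csgraph import connected_components

        totals = np.zeros(n)
        for _ in range(n_reps):
            keep = rng.random(len(edges)) < 0.5
            e = edges[keep]
            m = coo_matrix(
                (np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(n, n)
            )
            _, labels = connected_components(m, directed=False)
            sizes = np.bincount(labels)
            totals += sizes[labels] - 1
    return {v: totals[idx[v]] / n_reps for v in nodes}


def _bottleneck(adj_lists, nodes, n) -> np.ndarray:
    """Deterministic BFS-tree bottleneck counts."""
    score = np.zeros(n)
    for s in range(n):
        parent = np.full(n, -1, dtype=np.int64)
        order = []
        seen = np.zeros(n, dtype=bool)
        seen[s] = True
        q = deque([s])
        while q:
            u = q.popleft()
            order.append(u)
            for w in adj_lists[u]:
                if not seen[w]:
                    seen[w] = True
                    parent[w] = u
                    q.append(w)
        tree_nodes = len(order)
        if tree_nodes <= 1:
            continue
        subtree = np.ones(n)
        for u in reversed(order):
            if parent[u] >= 0:
                subtree[parent[u]] += subtree[u]
        thresh = tree_nodes / 4.0
        for u in order:
            if u != s and subtree[u] > thresh:
                score[u] += 1.0
    return score


def compute_centralities(
    graph: nx.Graph, epc_reps: int = 1000, seed: int = 0, max_nodes: int = 1000
) -> pd.DataFrame:
    """All 12 measures for every node; rows indexed by node, one column each."""
    n = graph.number_of_nodes()
    if n > max_nodes:
        raise ValueError(
            f"graph has {n} nodes (> max_nodes={max_nodes}); the exhaustive "
            "shortest-path measures need a smaller graph - subset it first"
        )
    nodes = sorted(graph.nodes)
    if n == 0:
        return pd.DataFrame(columns=MEASURES)
    idx = {v: i for i, v in enumerate(nodes)}
    adj_lists = [sorted(idx[w] for w in graph.neighbors(v)) for v in nodes]

    dist = np.full((n, n), -1, dtype=np.int64)
    sigma = np.zeros((n, n))
    for s in range(n):
        dist[s], sigma[s] = _bfs_counts(adj_lists, n, s)

    degree = np.array([len(a) for a in adj_lists], dtype=float)
    finite = dist >= 0
    inv_d = np.zeros_like(dist, dtype=float)
    off = finite & (dist > 0)
    inv_d[off] = 1.0 / dist[off]
    closeness = inv_d.sum(axis=1)

    ecc = np.zeros(n)
    radial = np.zeros(n)
    for comp in nx.connected_components(graph):
        ci = np.array(sorted(idx[v] for v in comp))
        if len(ci) == 1:
            continue
        sub_d = dist[np.ix_(ci, ci)]
        e = sub_d.max(axis=1)
        ecc[ci] = 1.0 / e
        diam = sub_d.max()
        radial[ci] = (diam + 1.0 - sub_d).sum(axis=1) - (diam + 1.0)
        radial[ci] /= len(ci) - 1.0

    betw = np.zeros(n)
    stress = np.zeros(n)
    triu = np.triu(np.ones((n, n), dtype=bool), 1)
    for v in range(n):
        dv = dist[v]
        on_path = (dv[:, None] + dv[None, :] == dist) & finite & (dv >= 0)[:, None]
        on_path[v, :] = False
        on_path[:, v] = False
        mask = on_path & triu
        prod = sigma[v][:, None] * sigma[v][None, :]
        stress[v] = prod[mask].sum()
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(sigma > 0, prod / np.where(sigma > 0, sigma, 1.0), 0.0)
        betw[v] = ratio[mask].sum()

    mcc = _mcc(graph, nodes)
    mnc = np.zeros(n)
    dmnc = np.zeros(n)
    for v in nodes:
        comp = _neighborhood_component(graph, v)
        if comp is None:
            continue
        size = comp.number_of_nodes()
        mnc[idx[v]] = size
        if size >= 2:
            dmnc[idx[v]] = comp.number_of_edges() / size**_DMNC_EPS
    epc = _epc(graph, nodes, epc_reps, seed)
    bottleneck = _bottleneck(adj_lists, nodes, n)
    clustering = nx.clustering(graph)

    return pd.DataFrame(
        {
            "Degree": degree,
            "MCC": [mcc[v] for v in nodes],
            "DMNC": dmnc,
            "MNC": mnc,
            "EPC": [epc[v] for v in nodes],
            "BottleNeck": bottleneck,
            "EcCentricity": ecc,
            "Closeness": closeness,
            "Radiality": radial,
            "Betweenness": betw,
            "Stress": stress,
            "ClusteringCoefficient": [clustering[v] for v in nodes],
        },
        index=pd.Index(nodes, name="node"),
    )


def select_hubs(table: pd.DataFrame, top_frac: float = 0.5) -> list:
    """Intersection of the top ``top_frac`` of nodes under every measure.

    Per measure, the top ceil(top_frac * n) nodes are kept, extended by every
    node tied with the boundary value (inclusive tie rule); the hub set is the
    intersection across all measures, sorted by node id.  Nodes with no edges
    (Degree 0) cannot be hubs and are dropped before ranking, so that their
    all-zero rows do not pull every boundary down to zero.
    """
    if len(table) == 0:
        return []
    if "Degree" in table.columns:
        table = table[table["Degree"] > 0]
        if len(table) == 0:
            return []
    n = len(table)
    k = int(np.ceil(top_frac * n))
    hubs = set(table.index)
    for col in table.columns:
        vals = table[col].sort_values(ascending=False)
        boundary = vals.iloc[k - 1]
        keep = set(table.index[table[col] >= boundary])
        hubs &= keep
    return sorted(hubs)
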