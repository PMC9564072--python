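"""Independent brute-force reference implementations used as test oracles.

Everything here is written from the definitions with naive enumeration; none
of it shares code with the package.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np


def floyd_warshall(g: nx.Graph, nodes):
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for u, v in g.edges:
        d[idx[u], idx[v]] = d[idx[v], idx[u]] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d, idx


def all_shortest_paths(g: nx.Graph, s, t, dist):
    """Enumerate shortest s-t paths recursively from the distance matrix."""
    if dist[s][t] == np.inf:
        return []
    if s == t:
        return [[s]]
    out = []
    for u in g.neighbors(s):
        if dist[u][t] == dist[s][t] - 1:
            out.extend([[s] + p for p in all_shortest_paths(g, u, t, dist)])
    return out


def centrality_oracles(g: nx.Graph, epc=False, epc_reps=1000, epc_seed=1):
    """Dict of measure -> {node: value}, by direct enumeration."""
    nodes = sorted(g.nodes)
    n = len(nodes)
    d, idx = floyd_warshall(g, nodes)
    dist_lookup = {u: {v: d[idx[u], idx[v]] for v in nodes} for u in nodes}

    degree = {v: g.degree(v) for v in nodes}

    # all maximal cliques by subset enumeration
    cliques = []
    for r in range(2, n + 1):
        for sub in itertools.combinations(nodes, r):
            if all(g.has_edge(a, b) for a, b in itertools.combinations(sub, 2)):
                cliques.append(set(sub))
    maximal = [c for c in cliques if not any(c < other for other in cliques)]
    mcc = {v: float(sum(math.factorial(len(c) - 1) for c in maximal if v in c))
           for v in nodes}

    mnc, dmnc = {}, {}
    for v in nodes:
        nbrs = set(g.neighbors(v))
        # enumerate connected neighbour subsets; keep the largest, preferring
        # more internal edges, then smaller labels (matching the package's
        # documented tie convention)
        candidates = []
        for r in range(1, len(nbrs) + 1):
            for sub in itertools.combinations(sorted(nbrs), r):
                sg = g.subgraph(sub)
                if nx.is_connected(sg):
                    candidates.append(sub)
        best = (
            set(
                min(
                    candidates,
                    key=lambda sub: (
                        -len(sub),
                        -g.subgraph(sub).number_of_edges(),
                        tuple(sorted(map(str, sub))),
                    ),
                )
            )
            if candidates
            else set()
        )
        mnc[v] = float(len(best))
        sg = g.subgraph(best)
        dmnc[v] = (
            sg.number_of_edges() / len(best) ** 1.7 if len(best) >= 2 else 0.0
        )

    # stress and betweenness by explicit shortest-path enumeration
    stress = {v: 0.0 for v in nodes}
    betw = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = all_shortest_paths(g, s, t, dist_lookup)
        if not paths:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            stress[v] += through
            betw[v] += through / len(paths)

    closeness = {
        v: float(sum(1.0 / dist_lookup[v][w] for w in nodes
                     if w != v and np.isfinite(dist_lookup[v][w])))
        for v in nodes
    }

    ecc, radial = {}, {}
    for comp in nx.connected_components(g):
        comp = sorted(comp)
        if len(comp) == 1:
            ecc[comp[0]] = 0.0
            radial[comp[0]] = 0.0
            continue
        diam = max(dist_lookup[a][b] for a in comp for b in comp)
        for v in comp:
            e = max(dist_lookup[v][w] for w in comp)
            ecc[v] = 1.0 / e
            radial[v] = sum(
                diam + 1.0 - dist_lookup[v][w] for w in comp if w != v
            ) / (len(comp) - 1.0)

    clustering = {}
    for v in nodes:
        nbrs = sorted(g.neighbors(v))
        k = len(nbrs)
        if k < 2:
            clustering[v] = 0.0
            continue
        links = sum(
            1 for a, b in itertools.combinations(nbrs, 2) if g.has_edge(a, b)
        )
        clustering[v] = 2.0 * links / (k * (k - 1))

    bottleneck = {v: 0.0 for v in nodes}
    for s in nodes:
        parent = bfs_tree_parents(g, s)
        tree_nodes = [w for w in nodes if w == s or parent.get(w) is not None]
        for v in tree_nodes:
            if v == s:
                continue
            below = 0
            for w in tree_nodes:
                x = w
                while x is not None:
                    if x == v:
                        below += 1
                        break
                    x = parent.get(x)
            if below > len(tree_nodes) / 4.0:
                bottleneck[v] += 1.0

    out = {
        "Degree": {v: float(degree[v]) for v in nodes},
        "MCC": mcc,
        "DMNC": dmnc,
        "MNC": mnc,
        "BottleNeck": bottleneck,
        "EcCentricity": ecc,
        "Closeness": closeness,
        "Radiality": radial,
        "Betweenness": betw,
        "Stress": stress,
        "ClusteringCoefficient": clustering,
    }
    if epc:
        out["EPC"] = epc_exact(g, nodes)
    return out


def bfs_tree_parents(g: nx.Graph, s):
    """Parents of the deterministic BFS tree (neighbours in sorted order)."""
    from collections import deque

    parent = {s: None}
    q = deque([s])
    while q:
        u = q.popleft()
        for w in sorted(g.neighbors(u)):
            if w not in parent:
                parent[w] = u
                q.append(w)
    parent.pop(s)
    return parent


def epc_exact(g: nx.Graph, nodes, chunk=1 << 15):
    """Exact expected reachable-count under independent 0.5 edge percolation.

    Enumerates all 2^E edge subsets (vectorized in chunks), so only usable for
    small graphs.
    """
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    edges = [(idx[u], idx[v]) for u, v in g.edges]
    m = len(edges)
    if m == 0:
        return {v: 0.0 for v in nodes}
    totals = np.zeros(n)
    masks = np.arange(1 << m, dtype=np.int64)
    for start in range(0, 1 << m, chunk):
        blk = masks[start : start + chunk]
        keep = ((blk[:, None] >> np.arange(m)[None, :]) & 1).astype(np.float32)
        reach = np.broadcast_to(
            np.eye(n, dtype=np.float32), (len(blk), n, n)
        ).copy()
        e = np.array(edges)
        reach[:, e[:, 0], e[:, 1]] = keep
        reach[:, e[:, 1], e[:, 0]] = keep
        for _ in range(max(1, int(np.ceil(np.log2(max(n, 2)))))):
            reach = (reach @ reach > 0).astype(np.float32)
        totals += reach.sum(axis=2).sum(axis=0) - len(blk)
    probs = totals / (1 << m)
    return {v: float(probs[idx[v]]) for v in nodes}
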