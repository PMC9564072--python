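"""Branching pseudo-time inference over a principal graph.

The trajectory is a minimum spanning tree over micro-cluster centroids
(k-means) in PC space.  Cells are projected onto the nearest tree edge; their
pseudo-time is the arc length from the root to the projection point.  The
branch point is the earliest degree->=3 vertex; its two largest downstream
subtrees become Path I and Path II, with Path II the arm whose terminal cells
carry the later mean clinical stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .sim import PATH_I, PATH_II, PRE, STAGES

__all__ = [
    "Trajectory",
    "learn_principal_graph",
    "root_and_order",
    "detect_branch_and_paths",
    "cluster_pseudotime",
]

_STAGE_NUM = {s: i + 1 for i, s in enumerate(STAGES)}


@dataclass
class Trajectory:
    """Per-cell pseudo-time and branch labels plus the principal graph."""

    pseudotime: pd.Series  # >= 0, 0 at the root
    branch: pd.Series  # PRE / PATH_I / PATH_II
    graph: Optional[nx.Graph]  # nodes carry 'pos'; edges carry 'weight'
    root_vertex: Optional[int]
    branch_vertex: Optional[int] = None
    cell_edge: Optional[pd.DataFrame] = None  # columns u, v, s (edge offset)
    vertex_time: Optional[dict] = field(default=None, repr=False)


def learn_principal_graph(
    scores, clusters: pd.Series, granularity: int = 50, seed: int = 0
) -> nx.Graph:
    """MST over k-means micro-cluster centroids in PC space."""
    if granularity < 3:
        raise ValueError("granularity must be >= 3")
    if clusters is not None and pd.Series(clusters).nunique() < 3:
        raise ValueError("at least 3 cell clusters required")
    x = np.asarray(scores, dtype=float)
    granularity = min(granularity, x.shape[0])
    km = KMeans(n_clusters=granularity, random_state=int(seed), n_init=10)
    km.fit(x)
    centroids = km.cluster_centers_
    g = nx.Graph()
    for i, c in enumerate(centroids):
        g.add_node(i, pos=c)
    d = np.linalg.norm(centroids[:, None] - centroids[None, :], axis=-1)
    complete = nx.Graph()
    for i in range(granularity):
        for j in range(i + 1, granularity):
            complete.add_edge(i, j, weight=float(d[i, j]))
    mst = nx.minimum_spanning_tree(complete)
    g.add_weighted_edges_from(
        (u, v, complete[u][v]["weight"]) for u, v in mst.edges
    )
    return g


def _project_cells(tree: nx.Graph, x: np.ndarray, vtime: dict):
    """Nearest-edge projection; ties go to the edge whose nearer vertex is earlier."""
    edges = list(tree.edges)
    pos = {v: np.asarray(tree.nodes[v]["pos"], dtype=float) for v in tree.nodes}
    n = x.shape[0]
    best = np.full(n, np.inf)
    best_edge = np.zeros((n, 2), dtype=int)
    best_s = np.zeros(n)
    order = sorted(
        edges, key=lambda e: (min(vtime[e[0]], vtime[e[1]]), max(vtime[e[0]], vtime[e[1]]))
    )
    for u, v in order:
        pu, pv = pos[u], pos[v]
        seg = pv - pu
        denom = float(seg @ seg)
        s = np.clip((x - pu) @ seg / denom, 0.0, 1.0) if denom > 0 else np.zeros(n)
        proj = pu + s[:, None] * seg
        dist = np.linalg.norm(x - proj, axis=1)
        better = dist < best - 1e-12  # earlier edges win exact ties
        best[better] = dist[better]
        best_edge[better] = (u, v)
        best_s[better] = s[better]
    return best_edge, best_s


def root_and_order(
    tree: nx.Graph, scores, stage_labels: Optional[pd.Series] = None, root: Optional[int] = None
) -> Trajectory:
    """Root the tree, project cells onto it, and compute arc-length pseudo-time.

    The root is the leaf vertex whose assigned cells are most enriched for the
    earliest observed stage (ties broken by cell count, then vertex id); only
    leaves are eligible because a trajectory origin is an endpoint of the
    principal graph -- rooting at an interior vertex leaves earlier cells
    dangling behind the root as a spurious arm.  An explicit ``root``
    overrides this and is required when no stage labels are given.
    """
    if isinstance(scores, pd.DataFrame):
        index, x = scores.index, scores.to_numpy(dtype=float)
    else:
        x = np.asarray(scores, dtype=float)
        index = pd.RangeIndex(x.shape[0])
    pos = np.array([tree.nodes[v]["pos"] for v in sorted(tree.nodes)])
    vids = np.array(sorted(tree.nodes))
    nearest = vids[
        np.argmin(np.linalg.norm(x[:, None, :] - pos[None, :, :], axis=-1), axis=1)
    ]

    if root is None:
        if stage_labels is None:
            raise ValueError("root must be supplied when stage labels are absent")
        stages = pd.Series(stage_labels).reindex(index)
        earliest = min(stages.dropna().unique(), key=lambda s: _STAGE_NUM[s])
        leaves = [v for v in tree.nodes if tree.degree(v) <= 1] or list(tree.nodes)
        frac, count = {}, {}
        for v in leaves:
            mask = nearest == v
            count[v] = int(mask.sum())
            frac[v] = float((stages[mask] == earliest).mean()) if count[v] else -1.0
        root = max(leaves, key=lambda v: (frac[v], count[v], -v))

    vtime = nx.single_source_dijkstra_path_length(tree, root, weight="weight")
    edge_uv, s = _project_cells(tree, x, vtime)
    pseudo = np.empty(x.shape[0])
    for i in range(x.shape[0]):
        u, v = edge_uv[i]
        if vtime[u] <= vtime[v]:  # v is downstream of u on the rooted tree
            pseudo[i] = vtime[u] + s[i] * tree[u][v]["weight"]
        else:
            pseudo[i] = vtime[v] + (1.0 - s[i]) * tree[u][v]["weight"]
    cell_edge = pd.DataFrame(
        {"u": edge_uv[:, 0], "v": edge_uv[:, 1], "s": s}, index=index
    )
    return Trajectory(
        pseudotime=pd.Series(pseudo, index=index, name="pseudotime"),
        branch=pd.Series(PRE, index=index, name="branch"),
        graph=tree,
        root_vertex=root,
        cell_edge=cell_edge,
        vertex_time=dict(vtime),
    )


def _arm_components(tree: nx.Graph, branch_vertex: int, root: int):
    """Downstream subtrees hanging off the branch vertex (root side excluded)."""
    cut = tree.copy()
    cut.remove_node(branch_vertex)
    comps = [set(c) for c in nx.connected_components(cut)]
    return [c for c in comps if root not in c]


def _arm_stats_at(traj: Trajectory, v: int):
    """(cell count, depth) of each downstream subtree hanging off vertex v."""
    arms = _arm_components(traj.graph, v, traj.root_vertex)
    edge_df = traj.cell_edge
    vtime = traj.vertex_time
    stats = []
    for comp in arms:
        in_comp = edge_df["u"].isin(comp) | edge_df["v"].isin(comp)
        depth = max(vtime[w] for w in comp) - vtime[v]
        stats.append((int(in_comp.sum()), depth))
    return stats


def detect_branch_and_paths(
    traj: Trajectory,
    stage_labels: Optional[pd.Series] = None,
    min_arm_frac: float = 0.15,
    min_depth_ratio: float = 0.3,
) -> Trajectory:
    """Find the branch point and split downstream cells into Path I and II.

    The branch point is the earliest (smallest pseudo-time) degree->=3 vertex
    among those whose two largest downstream subtrees each hold at least
    ``min_arm_frac`` of the cells (default 0.15: each path must carry a
    substantial share of the population) and have comparable depth (the
    shallower arm reaching at least ``min_depth_ratio`` of the deeper one's
    extent) -- the guards skip the spurious side-spurs and fat dead-ends an
    MST grows in noisy data, which subtend cells but do not progress in
    pseudo-time the way a genuine developmental path does.  Path II is the arm
    whose terminal cells (top 10% of the arm's arc length) have the later mean
    stage; ties go to the longer arm.  With more than two arms, the extra arms
    are merged into the geometrically nearest kept arm.
    """
    tree, root = traj.graph, traj.root_vertex
    vtime = traj.vertex_time
    n_cells = len(traj.pseudotime)
    min_cells = max(2.0, min_arm_frac * n_cells)
    candidates = []
    fallback = [v for v in tree.nodes if tree.degree(v) >= 3]
    for v in fallback:
        stats = sorted(_arm_stats_at(traj, v), reverse=True)  # by cell count
        if len(stats) < 2 or stats[1][0] < min_cells:
            continue
        d1, d2 = stats[0][1], stats[1][1]
        if min(d1, d2) >= min_depth_ratio * max(d1, d2):
            candidates.append(v)
    if not fallback:
        warnings.warn("no branch point found; trajectory is linear, all cells PRE")
        traj.branch_vertex = None
        return traj
    if not candidates:
        candidates = fallback
    bv = min(candidates, key=lambda v: (vtime[v], v))
    traj.branch_vertex = bv

    arms = _arm_components(tree, bv, root)
    # attach each downstream cell to an arm via its projected edge
    edge_df = traj.cell_edge
    cell_arm = np.full(len(edge_df), -1)
    for ai, comp in enumerate(arms):
        in_comp = edge_df["u"].isin(comp) | edge_df["v"].isin(comp)
        cell_arm[in_comp.to_numpy()] = ai
    sizes = [int((cell_arm == ai).sum()) for ai in range(len(arms))]
    keep = sorted(range(len(arms)), key=lambda ai: -sizes[ai])[:2]
    if len(arms) > 2:
        warnings.warn(
            f"{len(arms)} arms at the branch vertex; merging the "
            f"{len(arms) - 2} smallest into the nearest kept arm"
        )
        pos = {v: np.asarray(tree.nodes[v]["pos"]) for v in tree.nodes}

        def arm_start(ai):
            comp = arms[ai]
            start = min(comp, key=lambda v: vtime[v])
            return pos[start]

        for ai in range(len(arms)):
            if ai in keep:
                continue
            target = min(
                keep, key=lambda k: float(np.linalg.norm(arm_start(ai) - arm_start(k)))
            )
            cell_arm[cell_arm == ai] = target

    def arm_stats(ai):
        comp = arms[ai]
        length = max(vtime[v] for v in comp) - vtime[bv]
        mask = cell_arm == ai
        pt = traj.pseudotime.to_numpy()[mask]
        mean_term_stage = 0.0
        if stage_labels is not None and mask.any():
            # terminal half of the arm's arc: wide enough to average stages
            cutoff = pt.max() - 0.5 * max(pt.max() - vtime[bv], 1e-12)
            term = traj.pseudotime.index[mask][pt >= cutoff]
            nums = [_STAGE_NUM[s] for s in pd.Series(stage_labels).loc[term]]
            mean_term_stage = float(np.mean(nums)) if nums else 0.0
        return mean_term_stage, length

    a, b = keep
    stage_a, len_a = arm_stats(a)
    stage_b, len_b = arm_stats(b)
    if (stage_b, len_b) >= (stage_a, len_a):
        path2, path1 = b, a
    else:
        path2, path1 = a, b
    labels = np.full(len(edge_df), PRE, dtype=object)
    labels[cell_arm == path1] = PATH_I
    labels[cell_arm == path2] = PATH_II
    traj.branch = pd.Series(labels, index=traj.pseudotime.index, name="branch")
    return traj


def cluster_pseudotime(traj: Trajectory, clusters: pd.Series) -> pd.Series:
    """T_i: arithmetic mean pseudo-time of the cells in each cluster."""
    cl = pd.Series(clusters).reindex(traj.pseudotime.index)
    t = traj.pseudotime.groupby(cl).mean()
    t.index.name = "cluster"
    t.name = "T"
    return t
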