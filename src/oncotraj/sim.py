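"""Synthetic data generator for the branching-trajectory analysis.

Emulates the statistical structure of the real inputs (tumour scRNA-seq with a
one-branch-point developmental trajectory, a bulk cohort that mixes the cell
clusters, survival times driven by the patient pseudo-time score, a cell-line
drug-response reference, and PPI / receptor-ligand fixture files) with the
ground truth exposed so that every downstream stage can be tested for recovery.

Cells live on a Y-shaped topology: a trunk from pseudo-time 0 to the branch
point, then two arms (Path I and Path II).  Counts are negative binomial with a
log-scale mean built from a per-gene baseline, cluster-marker effects and
branch x time effects for the planted branch genes; ``dispersion=0`` gives the
Poisson limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import anndata as ad
import numpy as np
import pandas as pd
from scipy.optimize import brentq

PRE = "PRE"
PATH_I = "PATH_I"
PATH_II = "PATH_II"
STAGES = ["I", "II", "III", "IV"]

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_single_cells",
    "simulate_bulk_cohort",
    "simulate_survival",
    "simulate_drug_reference",
    "simulate_network_and_pairs",
    "PRE",
    "PATH_I",
    "PATH_II",
    "STAGES",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic world.

    The defaults describe a cohort-scale scenario: 10 clusters tiling the Y
    topology, a branch point at 40% of a 20-unit pseudo-time span (so patient
    scores land in the 0-20 range), moderate NB overdispersion, and Dirichlet(1)
    bulk mixtures with log-scale noise.
    """

    n_genes: int = 1500
    n_cells: int = 600
    n_clusters: int = 10
    branch_time: float = 0.4  # fraction of the total span, strictly in (0,1)
    n_marker_genes_per_cluster: int = 20
    n_branch_genes: int = 50
    n_gradient_genes: int = 150  # smooth lineage-wide programs along pseudo-time
    dispersion: float = 0.3  # NB: var = m + dispersion * m^2; 0 -> Poisson
    library_size_cv: float = 0.2
    n_bulk_samples: int = 50
    dirichlet_alpha: float = 1.0  # np.inf -> equal weights
    bulk_noise_sd: float = 0.2
    hazard_beta: float = 1.0  # effect of (S - mean S) on the log hazard
    censor_rate: float = 0.3
    n_cell_lines: int = 40
    n_drugs: int = 20
    seed: int = 0
    # world constants beyond the core knobs
    total_time: float = 20.0  # pseudo-time units over the whole trajectory
    marker_effect: float = 2.0  # natural-log bump of a marker in its cluster
    marker_width: float = 0.75  # bump SD in units of the cluster's segment length
    branch_effect: float = 2.0  # natural-log amplitude of branch genes at arm end
    gradient_effect: float = 1.5  # natural-log swing of gradient genes over the span
    path2_speedup: float = 1.5  # Path II progresses to stage IV faster
    n_patients: int = 10
    baseline_median_survival: float = 1000.0  # days at the mean score
    drug_noise_sd: float = 0.1

    def validate(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_cells": self.n_cells,
            "n_clusters": self.n_clusters,
            "n_marker_genes_per_cluster": self.n_marker_genes_per_cluster,
            "n_bulk_samples": self.n_bulk_samples,
            "n_cell_lines": self.n_cell_lines,
            "n_drugs": self.n_drugs,
            "n_patients": self.n_patients,
        }
        for name, v in counts.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if self.n_branch_genes < 0:
            raise ValueError("n_branch_genes must be >= 0")
        if not (0.0 < self.branch_time < 1.0):
            raise ValueError("branch_time must lie strictly inside (0, 1)")
        if self.n_clusters < 4:
            raise ValueError(
                "n_clusters must be >= 4 (one trunk cluster plus at least one "
                "per arm and a branch neighbourhood)"
            )
        if self.dispersion < 0 or self.library_size_cv < 0 or self.bulk_noise_sd < 0:
            raise ValueError("dispersion, library_size_cv, bulk_noise_sd must be >= 0")
        if not (0.0 <= self.censor_rate < 1.0):
            raise ValueError("censor_rate must be in [0, 1)")
        if not np.isfinite(self.hazard_beta):
            raise ValueError("hazard_beta must be finite")
        if self.n_gradient_genes < 0:
            raise ValueError("n_gradient_genes must be >= 0")
        needed = (
            self.n_clusters * self.n_marker_genes_per_cluster
            + self.n_branch_genes
            + self.n_gradient_genes
        )
        if needed > self.n_genes:
            raise ValueError(
                f"n_genes={self.n_genes} too small for {needed} "
                "marker+branch+gradient genes"
            )

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=int(seed))


@dataclass
class GroundTruth:
    """Hidden state of a simulated dataset, for recovery tests."""

    cluster: pd.Series  # per-cell cluster id, 1..K
    pseudotime: pd.Series  # per-cell true pseudo-time, >= 0
    branch: pd.Series  # per-cell PRE / PATH_I / PATH_II
    stage: pd.Series
    marker_genes: dict  # gene -> cluster id
    branch_genes: pd.DataFrame  # columns: gene, up_path
    gene_log_mean: pd.Series  # baseline natural-log mean per gene
    cluster_path: dict  # cluster id -> PRE / PATH_I / PATH_II
    proportions: Optional[pd.DataFrame] = None  # sample x cluster simplex rows
    effective_drugs: dict = field(default_factory=dict)
    hub_gene: Optional[str] = None
    rl_planted: Optional[dict] = None

    def to_trajectory(self):
        """A :class:`~oncotraj.trajectory.Trajectory` view of the true state."""
        from .trajectory import Trajectory

        return Trajectory(
            pseudotime=self.pseudotime.copy(),
            branch=self.branch.copy(),
            graph=None,
            root_vertex=None,
            branch_vertex=None,
        )

    def cluster_pseudotime(self) -> pd.Series:
        t = self.pseudotime.groupby(self.cluster).mean()
        t.index.name = "cluster"
        return t


def _cluster_layout(config: SimConfig):
    """Contiguous tiling of clusters over trunk / arm I / arm II."""
    k = config.n_clusters
    n_trunk = max(1, round(k * config.branch_time))
    n_trunk = min(n_trunk, k - 2)
    rem = k - n_trunk
    k1 = (rem + 1) // 2
    k2 = rem - k1
    return n_trunk, k1, k2


def _assign_clusters(t_frac, branch, config: SimConfig):
    n_trunk, k1, k2 = _cluster_layout(config)
    b = config.branch_time
    cl = np.zeros(t_frac.shape, dtype=int)
    trunk = branch == PRE
    idx = np.minimum((t_frac[trunk] / b * n_trunk).astype(int), n_trunk - 1)
    cl[trunk] = 1 + idx
    for arm, karm, offset in ((PATH_I, k1, n_trunk), (PATH_II, k2, n_trunk + k1)):
        m = branch == arm
        s = (t_frac[m] - b) / (1.0 - b)
        idx = np.minimum((s * karm).astype(int), karm - 1)
        cl[m] = offset + 1 + idx
    return cl


def simulate_single_cells(config: SimConfig) -> tuple[ad.AnnData, GroundTruth]:
    """Simulate counts for cells on a Y-shaped branching trajectory.

    Returns an AnnData (cells x genes, raw counts in ``X`` and
    ``layers["counts"]``) with ``patient`` and ``stage`` in ``obs``, plus the
    :class:`GroundTruth`.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    n, g = config.n_cells, config.n_genes
    b = config.branch_time

    t_frac = rng.uniform(0.0, 1.0, n)
    arm_draw = rng.integers(0, 2, n)
    branch = np.where(
        t_frac < b, PRE, np.where(arm_draw == 0, PATH_I, PATH_II)
    ).astype(object)
    pseudotime = t_frac * config.total_time
    cluster = _assign_clusters(t_frac, branch, config)

    # clinical progression: Path II reaches the advanced stages faster
    prog = t_frac.copy()
    m2 = branch == PATH_II
    prog[m2] = b + config.path2_speedup * (t_frac[m2] - b)
    qs = np.quantile(prog, [0.25, 0.5, 0.75])
    stage = np.array(STAGES, dtype=object)[np.searchsorted(qs, prog)]

    gene_ids = np.array([f"G{i + 1:05d}" for i in range(g)])
    baseline = rng.normal(-1.0, 0.7, g)

    perm = rng.permutation(g)
    n_mark = config.n_clusters * config.n_marker_genes_per_cluster
    marker_idx = perm[:n_mark].reshape(config.n_clusters, -1)
    branch_idx = perm[n_mark : n_mark + config.n_branch_genes]

    # markers are smooth bumps centred on the cluster's segment of the
    # topology, so expression similarity decays with distance along the tree
    # (adjacent clusters share shoulders, as in real developmental programs)
    n_trunk, k1, k2 = _cluster_layout(config)
    seg_len = {}
    centers = {}  # cluster -> (lineage, centre t)
    for c in range(1, config.n_clusters + 1):
        if c <= n_trunk:
            seg = b / n_trunk
            centers[c] = (PRE, (c - 0.5) * seg)
        elif c <= n_trunk + k1:
            seg = (1.0 - b) / k1
            centers[c] = (PATH_I, b + (c - n_trunk - 0.5) * seg)
        else:
            seg = (1.0 - b) / k2
            centers[c] = (PATH_II, b + (c - n_trunk - k1 - 0.5) * seg)
        seg_len[c] = seg

    def topo_dist(lineage_c, t_c):
        other_arm = (
            ((branch == PATH_I) & (lineage_c == PATH_II))
            | ((branch == PATH_II) & (lineage_c == PATH_I))
        )
        d = np.abs(t_frac - t_c)
        if lineage_c in (PATH_I, PATH_II):
            d = np.where(other_arm, (t_frac - b) + (t_c - b), d)
        return d

    log_mu = np.tile(baseline, (n, 1))
    marker_genes: dict[str, int] = {}
    for c in range(1, config.n_clusters + 1):
        lineage_c, t_c = centers[c]
        sigma = config.marker_width * seg_len[c]
        bump = config.marker_effect * np.exp(
            -0.5 * (topo_dist(lineage_c, t_c) / sigma) ** 2
        )
        log_mu[:, marker_idx[c - 1]] += bump[:, None]
        for j in marker_idx[c - 1]:
            marker_genes[gene_ids[j]] = c

    # branch genes: opposite linear-in-time effects on the two arms
    s_arm = np.clip((t_frac - b) / (1.0 - b), 0.0, None)
    sign = np.where(branch == PATH_II, 1.0, np.where(branch == PATH_I, -1.0, 0.0))
    up_paths = []
    for i, j in enumerate(branch_idx):
        up = PATH_II if i % 2 == 0 else PATH_I
        up_paths.append(up)
        gene_sign = 1.0 if up == PATH_II else -1.0
        log_mu[:, j] += gene_sign * sign * s_arm * config.branch_effect
    branch_df = pd.DataFrame(
        {"gene": gene_ids[branch_idx], "up_path": up_paths}
    )

    # gradient genes: smooth programs shared by both lineages, linear in t
    n_used = n_mark + config.n_branch_genes
    grad_idx = perm[n_used : n_used + config.n_gradient_genes]
    if len(grad_idx):
        slopes = rng.choice([-1.0, 1.0], len(grad_idx)) * config.gradient_effect
        log_mu[:, grad_idx] += (t_frac - 0.5)[:, None] * slopes[None, :]

    if config.library_size_cv > 0:
        s2 = math.log1p(config.library_size_cv**2)
        lib = rng.lognormal(-s2 / 2.0, math.sqrt(s2), n)
    else:
        lib = np.ones(n)
    mean = lib[:, None] * np.exp(log_mu)
    if config.dispersion > 0:
        lam = rng.gamma(1.0 / config.dispersion, mean * config.dispersion)
        counts = rng.poisson(lam).astype(np.float64)
    else:
        counts = rng.poisson(mean).astype(np.float64)

    cell_ids = [f"C{i + 1:05d}" for i in range(n)]
    patients = np.array([f"P{j + 1:02d}" for j in rng.integers(0, config.n_patients, n)])
    obs = pd.DataFrame({"patient": patients, "stage": stage}, index=cell_ids)
    adata = ad.AnnData(X=counts, obs=obs, var=pd.DataFrame(index=gene_ids))
    adata.layers["counts"] = counts.copy()
    adata.uns["layer"] = "counts"

    n_trunk, k1, k2 = _cluster_layout(config)
    cluster_path = {c + 1: PRE for c in range(n_trunk)}
    cluster_path.update({n_trunk + 1 + i: PATH_I for i in range(k1)})
    cluster_path.update({n_trunk + k1 + 1 + i: PATH_II for i in range(k2)})

    idx = pd.Index(cell_ids)
    truth = GroundTruth(
        cluster=pd.Series(cluster, index=idx, name="cluster"),
        pseudotime=pd.Series(pseudotime, index=idx, name="pseudotime"),
        branch=pd.Series(branch.astype(str), index=idx, name="branch"),
        stage=pd.Series(stage.astype(str), index=idx, name="stage"),
        marker_genes=marker_genes,
        branch_genes=branch_df,
        gene_log_mean=pd.Series(baseline, index=gene_ids, name="log_mean"),
        cluster_path=cluster_path,
    )
    return adata, truth


def cluster_profiles(adata: ad.AnnData, cluster: pd.Series) -> pd.DataFrame:
    """Per-cluster mean log-normalized expression (genes x clusters)."""
    from .preprocess import normalize_log

    if adata.uns.get("layer") == "counts":
        adata = normalize_log(adata)
    x = np.asarray(adata.X)
    labels = cluster.loc[adata.obs_names].to_numpy()
    out = {}
    for c in np.unique(labels):
        out[int(c)] = x[labels == c].mean(axis=0)
    return pd.DataFrame(out, index=adata.var_names)


def simulate_bulk_cohort(
    adata: ad.AnnData, truth: GroundTruth, config: SimConfig
) -> tuple[pd.DataFrame, GroundTruth]:
    """Bulk samples as Dirichlet mixtures of cluster mean log-profiles.

    Each sample is ``M @ w + N(0, bulk_noise_sd)`` on the log scale, where M
    holds the cluster mean log-normalized profiles.  ``dirichlet_alpha=np.inf``
    degenerates to equal weights.  Mixture weights are recorded in
    ``truth.proportions``.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    profiles = cluster_profiles(adata, truth.cluster)
    k = profiles.shape[1]
    if np.isinf(config.dirichlet_alpha):
        w = np.full((config.n_bulk_samples, k), 1.0 / k)
    else:
        w = rng.dirichlet(np.full(k, config.dirichlet_alpha), config.n_bulk_samples)
    bulk = profiles.to_numpy() @ w.T
    if config.bulk_noise_sd > 0:
        bulk = bulk + rng.normal(0.0, config.bulk_noise_sd, bulk.shape)
    samples = [f"S{i + 1:04d}" for i in range(config.n_bulk_samples)]
    bulk_df = pd.DataFrame(bulk, index=profiles.index, columns=samples)
    truth.proportions = pd.DataFrame(w, index=samples, columns=profiles.columns)
    return bulk_df, truth


def _expected_censor_frac(tau: float, rates: np.ndarray) -> float:
    # P(C < T) for T ~ Exp(rate), C ~ U(0, tau)
    x = rates * tau
    return float(np.mean((1.0 - np.exp(-x)) / x))


def simulate_survival(scores: pd.Series, config: SimConfig) -> pd.DataFrame:
    """Exponential survival with log-hazard linear in the (centred) score.

    Censoring is independent uniform on [0, tau] with tau solved numerically so
    the expected censored fraction equals ``censor_rate``.
    """
    if not np.isfinite(config.hazard_beta):
        raise ValueError("hazard_beta must be finite")
    s = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    rng = np.random.default_rng([config.seed, 2])
    h0 = math.log(2.0) / config.baseline_median_survival
    rates = h0 * np.exp(config.hazard_beta * (s - s.mean()))
    t_event = rng.exponential(1.0 / rates)
    if config.censor_rate <= 0:
        time, event = t_event, np.ones(len(s), dtype=int)
    else:
        hi = 1.0
        while _expected_censor_frac(hi, rates) > config.censor_rate:
            hi *= 2.0
            if hi > 1e12:
                break
        tau = brentq(
            lambda t: _expected_censor_frac(t, rates) - config.censor_rate, 1e-9, hi
        )
        c = rng.uniform(0.0, tau, len(s))
        event = (t_event <= c).astype(int)
        time = np.minimum(t_event, c)
    time = np.maximum(time, 1e-6)
    return pd.DataFrame(
        {"time": time, "event": event}, index=pd.Index(scores.index, name="sample_id")
    )


def simulate_drug_reference(
    truth: GroundTruth, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Cell-line expression, drug logFC responses and a drug-target table.

    Responses are linear in (centred) log expression: ``logFC = b0 + w.x + eps``.
    Three drugs are planted: one blocking drug loading negatively on the
    Path II-up branch genes, one cluster-specific drug loading negatively on
    the terminal Path II cluster's markers, and one all-zero null drug.
    Planted identities are recorded in ``truth.effective_drugs``.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 3])
    genes = truth.gene_log_mean.index
    baseline = truth.gene_log_mean.to_numpy()
    lines = [f"CL{i + 1:03d}" for i in range(config.n_cell_lines)]
    x = baseline[None, :] + rng.normal(0.0, 1.0, (config.n_cell_lines, len(genes)))
    expr = pd.DataFrame(x, index=lines, columns=genes)

    path2_up = truth.branch_genes.loc[
        truth.branch_genes["up_path"] == PATH_II, "gene"
    ].tolist()[:20]
    terminal_cluster = max(
        (c for c, p in truth.cluster_path.items() if p == PATH_II), default=None
    )
    target_cluster_markers = [
        g for g, c in truth.marker_genes.items() if c == terminal_cluster
    ]

    drug_ids = [f"D{i + 1:03d}" for i in range(config.n_drugs)]
    names, rows, resp = [], [], {}
    centred = x - baseline[None, :]
    gene_pos = {g: i for i, g in enumerate(genes)}
    for i, did in enumerate(drug_ids):
        w = np.zeros(len(genes))
        if i == 0 and path2_up:
            name, b0 = "planted_blocking", -1.0
            w[[gene_pos[g] for g in path2_up]] = -0.6
            truth.effective_drugs[did] = {"kind": "blocking", "path": PATH_II}
        elif i == 1 and target_cluster_markers:
            name, b0 = "planted_cluster_specific", -1.0
            w[[gene_pos[g] for g in target_cluster_markers]] = -0.6
            truth.effective_drugs[did] = {
                "kind": "cluster_specific",
                "clusters": [terminal_cluster],
            }
        elif i == 2:
            name, b0 = "null_drug", 0.0
        else:
            name = f"drug_{i + 1}"
            b0 = float(rng.normal(0.0, 0.2))
            w[rng.choice(len(genes), 3, replace=False)] = rng.normal(0.0, 0.3, 3)
        names.append(name)
        eps = (
            rng.normal(0.0, config.drug_noise_sd, config.n_cell_lines)
            if config.drug_noise_sd > 0
            else 0.0
        )
        resp[did] = b0 + centred @ w + eps
        for j in np.flatnonzero(w)[:10]:
            rows.append((did, name, genes[j]))
    response = pd.DataFrame(resp, index=lines)
    targets = pd.DataFrame(rows, columns=["drug_id", "drug_name", "target_gene"])
    return expr, response, targets


def simulate_network_and_pairs(
    truth: GroundTruth, config: SimConfig, max_nodes: int = 80
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """PPI edge list with a planted hub, and a receptor-ligand pair list.

    The hub (a Path II-up branch gene) is attached to every other node and sits
    in a 5-clique; more than half of the remaining nodes stay hub-only leaves so
    the hub survives the top-50% intersection rule in all 12 centralities.
    The planted RL pair links a marker of cluster 2 (ligand) to a marker of
    cluster 3 (receptor); decoy pairs use background genes.
    """
    rng = np.random.default_rng([config.seed, 4])
    branch_genes = truth.branch_genes["gene"].tolist()
    marker_genes = list(truth.marker_genes)
    path2_up = truth.branch_genes.loc[
        truth.branch_genes["up_path"] == PATH_II, "gene"
    ].tolist()
    hub = path2_up[0] if path2_up else (branch_genes + marker_genes)[0]
    nodes = [hub] + [g for g in branch_genes + marker_genes if g != hub]
    nodes = nodes[:max_nodes]
    n = len(nodes)

    edges = {(hub, v) for v in nodes[1:]}
    clique = nodes[: min(5, n)]
    for i in range(len(clique)):
        for j in range(i + 1, len(clique)):
            edges.add((clique[i], clique[j]))
    extra_pool = nodes[1 : max(2, int(0.2 * n))]
    for i in range(len(extra_pool)):
        for j in range(i + 1, len(extra_pool)):
            if rng.uniform() < 0.15:
                edges.add((extra_pool[i], extra_pool[j]))
    edge_rows = sorted(edges)
    edge_df = pd.DataFrame(edge_rows, columns=["gene_a", "gene_b"])
    edge_df["score"] = rng.uniform(0.4, 1.0, len(edge_df)).round(3)
    truth.hub_gene = hub

    by_cluster: dict[int, list[str]] = {}
    for g, c in truth.marker_genes.items():
        by_cluster.setdefault(c, []).append(g)
    lig = sorted(by_cluster[2])[0]
    rec = sorted(by_cluster[3])[0]
    background = [
        g
        for g in truth.gene_log_mean.index
        if g not in truth.marker_genes and g not in set(branch_genes)
    ]
    decoys = rng.choice(len(background), size=(14, 2), replace=False)
    pair_rows = [(lig, rec)] + [
        (background[a], background[b]) for a, b in decoys
    ]
    pairs = pd.DataFrame(pair_rows, columns=["ligand", "receptor"])
    truth.rl_planted = {"ligand": lig, "receptor": rec, "cluster_a": 2, "cluster_b": 3}
    return edge_df, pairs
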