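"""Convenience wrapper running the full analysis on one dataset."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from . import branch as branch_mod
from . import comm as comm_mod
from . import drugs as drugs_mod
from . import preprocess, scoring, trajectory as traj_mod
from .sim import (
    SimConfig,
    simulate_bulk_cohort,
    simulate_drug_reference,
    simulate_network_and_pairs,
    simulate_single_cells,
    simulate_survival,
)

__all__ = ["PipelineResult", "run_synthetic"]


@dataclass
class PipelineResult:
    adata: object
    truth: object
    clusters: pd.Series
    traj: object
    cluster_T: pd.Series
    beam: pd.DataFrame
    branch_gene_list: list
    comm_counts: pd.DataFrame
    deconv: object
    scores: object
    cutpoint: float
    logrank_p: float
    hubs: list
    screens: pd.DataFrame
    blocking: pd.DataFrame = field(default=None)
    cluster_specific: pd.DataFrame = field(default=None)
    extras: dict = field(default_factory=dict)


def run_synthetic(
    config: Optional[SimConfig] = None,
    seed: int = 0,
    n_hvg: int = 1000,
    n_pcs: int = 20,
    resolution: float = 0.8,
    granularity: int = 50,
    comm_n_perm: int = 500,
    deconv_n_perm: int = 100,
) -> PipelineResult:
    """Simulate a cohort and run every stage of the analysis on it.

    Sized for a desk-scale smoke run; each stage is the same code path the
    module-level API exposes.
    """
    if config is None:
        config = SimConfig(seed=seed)
    else:
        config = config.with_seed(seed)
    adata, truth = simulate_single_cells(config)
    bulk, truth = simulate_bulk_cohort(adata, truth, config)
    ref_expr, ref_resp, drug_targets = simulate_drug_reference(truth, config)
    edges, rl_pairs = simulate_network_and_pairs(truth, config)

    adata, qc = preprocess.qc_filter_patients(adata, min_cells=5)
    logn = preprocess.normalize_log(adata)
    hvg = preprocess.select_hvg(logn, n_hvg=min(n_hvg, logn.n_vars))
    scaled = preprocess.scale_genes(logn[:, hvg].copy())
    pcs, ev = preprocess.run_pca(scaled, n_components=min(n_pcs, len(hvg) - 1))
    clusters = preprocess.cluster_cells(pcs, resolution=resolution, seed=seed)

    tree = trajectory_graph = traj_mod.learn_principal_graph(
        pcs, clusters, granularity=min(granularity, logn.n_obs // 4), seed=seed
    )
    traj = traj_mod.root_and_order(tree, pcs, stage_labels=logn.obs["stage"])
    traj = traj_mod.detect_branch_and_paths(traj, stage_labels=logn.obs["stage"])
    cluster_t = traj_mod.cluster_pseudotime(traj, clusters)

    beam = branch_mod.beam_test(logn, traj)
    branch_genes = branch_mod.filter_branch_genes(beam)

    _, comm_counts = comm_mod.score_interactions(
        logn, clusters, rl_pairs, n_perm=comm_n_perm, seed=seed
    )

    sig = scoring.build_signature(logn, clusters, p_thr=0.01, lfc_thr=1.0)
    deconv = scoring.deconvolve(bulk, sig, n_perm=deconv_n_perm, seed=seed)
    score = scoring.pseudo_time_score(deconv.P, cluster_t)
    surv = simulate_survival(score.S, config)
    cut, groups, p = scoring.score_cutpoint_groups(score.S, surv)

    markers = drugs_mod.find_cluster_markers(logn, clusters)
    target_genes = sorted(set(markers["gene"]).union(branch_genes))
    net = drugs_mod.build_ppi_subnetwork(target_genes, edges)
    hubs = (
        drugs_mod.select_hubs(drugs_mod.compute_centralities(net, seed=seed))
        if net.number_of_edges()
        else []
    )
    screens = drugs_mod.predict_sensitivity(
        ref_expr, ref_resp, logn, clusters, traj=traj
    )
    blocking = drugs_mod.screen_blocking(screens)
    targeting = {}
    marker_cluster = dict(zip(markers["gene"], markers["cluster"]))
    mapped = drugs_mod.map_drugs(target_genes, drug_targets)
    for _, row in mapped.iterrows():
        cls = sorted({marker_cluster[g] for g in row["targets"] if g in marker_cluster})
        targeting[row["drug_id"]] = cls
    specific = drugs_mod.screen_cluster_specific(screens, targeting)

    return PipelineResult(
        adata=logn,
        truth=truth,
        clusters=clusters,
        traj=traj,
        cluster_T=cluster_t,
        beam=beam,
        branch_gene_list=branch_genes,
        comm_counts=comm_counts,
        deconv=deconv,
        scores=score,
        cutpoint=cut,
        logrank_p=p,
        hubs=hubs,
        screens=screens,
        blocking=blocking,
        cluster_specific=specific,
        extras={
            "qc": qc,
            "explained_variance": ev,
            "graph": trajectory_graph,
            "survival": surv,
            "groups": groups,
            "signature": sig,
        },
    )
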