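"""Cluster markers, PPI hub mining, branch-trend filtering and drug screening.

Candidate targets are cluster marker genes (AUROC + rank-sum screen) or
branch-driving genes; hubs are mined from the induced PPI subnetwork with the
top-50% intersection rule over 12 centralities; drugs mapped to the targets
are then validated by ridge-predicted per-cell sensitivities (logFC of
viability, more negative = more sensitive) and two screens: "blocking" drugs
(negative overall, more negative on Path II than Path I) and
"cluster-specific" drugs (negative overall, more negative on their targeted
clusters than elsewhere).
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import RidgeCV

from .centrality import compute_centralities, select_hubs  # noqa: F401
from .sim import PATH_I, PATH_II

__all__ = [
    "find_cluster_markers",
    "build_ppi_subnetwork",
    "compute_centralities",
    "select_hubs",
    "branch_trend_filter",
    "map_drugs",
    "predict_sensitivity",
    "screen_blocking",
    "screen_cluster_specific",
    "cluster_paths",
]


def find_cluster_markers(
    adata, clusters: pd.Series, auroc_min: float = 0.8, p_max: float = 0.01
) -> pd.DataFrame:
    """Per-cluster marker genes by AUROC and one-sided rank-sum p.

    For every gene and cluster, the AUROC of expression separating the cluster
    from the rest is the scaled Mann-Whitney U statistic; p is the one-sided
    (cluster > rest) rank-sum p.  Markers must pass auroc > auroc_min,
    p < p_max, and (as a stand-in for manual review) cluster mean > overall
    mean.
    """
    cl = pd.Series(clusters).reindex(adata.obs_names)
    x = np.asarray(adata.X, dtype=float)
    overall_mean = x.mean(axis=0)
    rows = []
    for c in sorted(cl.dropna().unique()):
        mask = (cl == c).to_numpy()
        n1, n2 = int(mask.sum()), int((~mask).sum())
        res = stats.mannwhitneyu(
            x[mask], x[~mask], axis=0, alternative="greater", method="asymptotic"
        )
        auroc = res.statistic / (n1 * n2)
        keep = (
            (auroc > auroc_min)
            & (res.pvalue < p_max)
            & (x[mask].mean(axis=0) > overall_mean)
        )
        for j in np.flatnonzero(keep):
            rows.append((adata.var_names[j], c, float(auroc[j]), float(res.pvalue[j])))
    return pd.DataFrame(rows, columns=["gene", "cluster", "auroc", "p"])


def build_ppi_subnetwork(genes, edges: pd.DataFrame) -> nx.Graph:
    """Induced subgraph of the PPI edge list on ``genes``; isolates retained."""
    genes = list(dict.fromkeys(genes))
    gene_set = set(genes)
    g = nx.Graph()
    g.add_nodes_from(genes)
    n_self = 0
    for a, b in zip(edges["gene_a"], edges["gene_b"]):
        if a == b:
            n_self += 1
            continue
        if a in gene_set and b in gene_set:
            g.add_edge(a, b)
    if n_self:
        warnings.warn(f"dropped {n_self} self-loop edges")
    return g


def branch_trend_filter(
    genes, adata, traj, rho_min: float = 0.2, p_max: float = 0.05
) -> list:
    """Genes rising along Path II and falling along Path I.

    Keeps genes with Spearman rho >= rho_min (p < p_max) against pseudo-time
    within Path II cells and rho <= -rho_min (p < p_max) within Path I cells.
    """
    cells = adata.obs_names.intersection(traj.branch.index)
    branch = traj.branch.loc[cells]
    t = traj.pseudotime.loc[cells].to_numpy()
    x = np.asarray(adata[cells].X, dtype=float)
    kept = []
    m1 = (branch == PATH_I).to_numpy()
    m2 = (branch == PATH_II).to_numpy()
    for gene in genes:
        j = adata.var_names.get_loc(gene)
        with warnings.catch_warnings():
            # constant genes yield NaN rho and are dropped below
            warnings.simplefilter("ignore", stats.ConstantInputWarning)
            r2, p2 = stats.spearmanr(x[m2, j], t[m2])
            r1, p1 = stats.spearmanr(x[m1, j], t[m1])
        if np.isnan(r1) or np.isnan(r2):
            continue
        if r2 >= rho_min and p2 < p_max and r1 <= -rho_min and p1 < p_max:
            kept.append(gene)
    return kept


def map_drugs(targets, table: pd.DataFrame) -> pd.DataFrame:
    """Drugs hitting any of ``targets``, ranked by number of matched targets."""
    targets = set(targets)
    hit = table[table["target_gene"].isin(targets)]
    if len(hit) == 0:
        return pd.DataFrame(columns=["drug_id", "drug_name", "targets", "n_targets"])
    grouped = (
        hit.groupby(["drug_id", "drug_name"])["target_gene"]
        .apply(lambda s: sorted(set(s)))
        .reset_index()
        .rename(columns={"target_gene": "targets"})
    )
    grouped["n_targets"] = grouped["targets"].str.len()
    return grouped.sort_values(
        ["n_targets", "drug_id"], ascending=[False, True], ignore_index=True
    )


def cluster_paths(traj, clusters: pd.Series) -> dict:
    """Cluster -> PRE / PATH_I / PATH_II by the majority branch of its cells."""
    cl = pd.Series(clusters).reindex(traj.branch.index)
    out = {}
    for c, grp in traj.branch.groupby(cl):
        out[c] = grp.value_counts().idxmax()
    return out


def predict_sensitivity(
    reference_expr: pd.DataFrame,
    reference_response: pd.DataFrame,
    adata,
    clusters: pd.Series,
    traj=None,
    ridge_alphas=None,
) -> pd.DataFrame:
    """Ridge-predicted per-cell drug sensitivity, averaged per cluster and path.

    Per drug, response is regressed on standardized shared-gene expression of
    the reference cell lines (penalty chosen by leave-one-out GCV over a fixed
    grid); the fit then scores every cell.  Returns one row per drug with the
    overall (cell-weighted) mean, per-cluster means and per-path means
    (unweighted over the path's clusters).  Drugs with fewer than 3 reference
    observations are skipped.
    """
    if ridge_alphas is None:
        ridge_alphas = np.logspace(-3, 3, 13)
    shared = reference_expr.columns.intersection(adata.var_names)
    if len(shared) < 10:
        raise ValueError(f"only {len(shared)} shared genes; need >= 10")
    ref = reference_expr[shared].to_numpy(dtype=float)
    mu, sd = ref.mean(axis=0), ref.std(axis=0)
    sd[sd == 0] = 1.0
    ref_z = (ref - mu) / sd
    sc = np.asarray(adata[:, shared].X, dtype=float)
    sc_z = (sc - mu) / sd

    cl = pd.Series(clusters).reindex(adata.obs_names)
    uniq = sorted(cl.dropna().unique())
    path_of = cluster_paths(traj, clusters) if traj is not None else {}

    rows = []
    for drug in reference_response.columns:
        y = reference_response[drug].to_numpy(dtype=float)
        ok = np.isfinite(y)
        if ok.sum() < 3:
            warnings.warn(f"drug {drug} has fewer than 3 reference observations; skipped")
            continue
        model = RidgeCV(alphas=ridge_alphas, fit_intercept=True)
        model.fit(ref_z[ok], y[ok])
        pred = model.predict(sc_z)
        row = {"drug_id": drug, "overall": float(pred.mean())}
        cmeans = {}
        for c in uniq:
            cmeans[c] = float(pred[(cl == c).to_numpy()].mean())
            row[f"cluster_{c}"] = cmeans[c]
        for path in (PATH_I, PATH_II):
            members = [c for c in uniq if path_of.get(c) == path]
            row[f"{path.lower()}_mean"] = (
                float(np.mean([cmeans[c] for c in members])) if members else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)


def screen_blocking(screens: pd.DataFrame) -> pd.DataFrame:
    """Blocking screen: overall mean logFC < 0 and Path II mean < Path I mean."""
    out = screens.copy()
    out["passes_blocking"] = (out["overall"] < 0) & (
        out["path_ii_mean"] < out["path_i_mean"]
    )
    return out


def screen_cluster_specific(screens: pd.DataFrame, targeting: dict) -> pd.DataFrame:
    """Cluster-specific screen: overall < 0 and targeted clusters more sensitive.

    ``targeting`` maps drug_id -> list of targeted cluster ids.  A drug passes
    when its overall mean logFC is below 0 and the mean over its targeted
    clusters is lower than the mean over the non-targeted clusters.
    """
    cluster_cols = [c for c in screens.columns if str(c).startswith("cluster_")]
    ids = [c.split("_", 1)[1] for c in cluster_cols]
    passes, t_means, nt_means = [], [], []
    for _, row in screens.iterrows():
        targets = {str(c) for c in targeting.get(row["drug_id"], [])}
        tvals = [row[f"cluster_{c}"] for c in ids if c in targets]
        nvals = [row[f"cluster_{c}"] for c in ids if c not in targets]
        tm = float(np.mean(tvals)) if tvals else np.nan
        nm = float(np.mean(nvals)) if nvals else np.nan
        t_means.append(tm)
        nt_means.append(nm)
        passes.append(
            bool(row["overall"] < 0 and tvals and nvals and tm < nm)
        )
    out = screens.copy()
    out["targeting_mean"] = t_means
    out["non_targeting_mean"] = nt_means
    out["passes_cluster_specific"] = passes
    return out
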