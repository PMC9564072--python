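"""Receptor-ligand communication scoring between cell clusters.

For an ordered cluster pair (a, b) and a ligand-receptor pair, the score is
the average of the ligand's mean expression in a and the receptor's mean
expression in b; the null distribution comes from permuting the cluster
labels.  Significant pairs (p < alpha and score > 0) are aggregated into an
interaction-count matrix between clusters.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["score_interactions"]


def _cluster_means(x: np.ndarray, labels: np.ndarray, uniq: np.ndarray) -> np.ndarray:
    """K x G matrix of per-cluster means (rows follow ``uniq``)."""
    onehot = (labels[None, :] == uniq[:, None]).astype(float)
    counts = onehot.sum(axis=1, keepdims=True)
    return (onehot @ x) / counts


def score_interactions(
    adata,
    clusters: pd.Series,
    pairs: pd.DataFrame,
    n_perm: int = 2000,
    seed: int = 0,
    restrict_clusters=None,
    alpha: float = 0.05,
    directed_counts: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Permutation test of receptor-ligand scores for all ordered cluster pairs.

    Returns (per-interaction results, cluster x cluster count matrix of
    significant pairs).  By default counts aggregate both directions into a
    symmetric matrix; set ``directed_counts`` for the directed version.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for usable p-value resolution")
    cl = pd.Series(clusters).reindex(adata.obs_names)
    if restrict_clusters is not None:
        keep = cl.isin(list(restrict_clusters))
        adata = adata[keep.to_numpy()]
        cl = cl[keep]
    labels = cl.to_numpy()
    uniq = np.unique(labels)

    missing = sorted(
        set(pairs["ligand"]).union(pairs["receptor"]) - set(adata.var_names)
    )
    if missing:
        warnings.warn(f"{len(missing)} pair genes absent from the matrix; skipped")
    ok = pairs["ligand"].isin(adata.var_names) & pairs["receptor"].isin(adata.var_names)
    pairs = pairs.loc[ok].reset_index(drop=True)
    genes = pd.Index(sorted(set(pairs["ligand"]).union(pairs["receptor"])))
    gpos = {g: i for i, g in enumerate(genes)}
    x = np.asarray(adata[:, genes].X, dtype=float)

    obs_means = _cluster_means(x, labels, uniq)
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, len(uniq), len(genes)))
    for r in range(n_perm):
        null[r] = _cluster_means(x, rng.permutation(labels), uniq)

    krange = range(len(uniq))
    rows = []
    for _, pr in pairs.iterrows():
        li, ri = gpos[pr["ligand"]], gpos[pr["receptor"]]
        for ia in krange:
            for ib in krange:
                s = 0.5 * (obs_means[ia, li] + obs_means[ib, ri])
                ns = 0.5 * (null[:, ia, li] + null[:, ib, ri])
                p = (1.0 + np.count_nonzero(ns >= s)) / (n_perm + 1.0)
                rows.append(
                    (uniq[ia], uniq[ib], pr["ligand"], pr["receptor"], s, p)
                )
    res = pd.DataFrame(
        rows, columns=["cluster_a", "cluster_b", "ligand", "receptor", "mean_score", "p"]
    )
    res["significant"] = (res["p"] < alpha) & (res["mean_score"] > 0)

    counts = pd.DataFrame(0, index=uniq, columns=uniq)
    sig = res[res["significant"]]
    for a, b in zip(sig["cluster_a"], sig["cluster_b"]):
        counts.loc[a, b] += 1
    if not directed_counts:
        sym = counts.to_numpy() + counts.to_numpy().T
        np.fill_diagonal(sym, np.diag(counts.to_numpy()))
        counts = pd.DataFrame(sym, index=uniq, columns=uniq)
    return res, counts
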