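"""QC, normalization, feature selection, PCA and graph clustering of cancer cells."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import igraph
import leidenalg
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "QCReport",
    "qc_filter_patients",
    "normalize_log",
    "select_hvg",
    "scale_genes",
    "run_pca",
    "elbow_select",
    "cluster_cells",
]


@dataclass
class QCReport:
    """Per-patient removal decisions: reason is 'low_cells' or 'non_normal'."""

    removed: list = field(default_factory=list)  # (patient, reason, n_cells, p)
    kept: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "removed": [
                {"patient": p, "reason": r, "n_cells": n, "shapiro_p": pv}
                for p, r, n, pv in self.removed
            ],
            "kept": list(self.kept),
        }


def _counts(adata: ad.AnnData) -> np.ndarray:
    if "counts" in adata.layers:
        return np.asarray(adata.layers["counts"])
    if adata.uns.get("layer", "counts") == "counts":
        return np.asarray(adata.X)
    raise ValueError("counts layer required")


def qc_filter_patients(
    adata: ad.AnnData, min_cells: int = 20, normality_alpha: float = 0.01
) -> tuple[ad.AnnData, QCReport]:
    """Drop patients with few cells or non-Gaussian per-cell total counts.

    A patient is removed when it has fewer than ``min_cells`` cells, or when a
    Shapiro-Wilk test on its cells' log total counts rejects normality at
    ``normality_alpha`` (log scale: totals are log-normal-ish in healthy data,
    so the test flags genuinely aberrant patients rather than benign skew).
    Mirrors the removal of low-cell patients whose expression totals depart
    from normality.
    """
    counts = _counts(adata)
    totals = np.log1p(counts.sum(axis=1))
    report = QCReport()
    keep_mask = np.zeros(adata.n_obs, dtype=bool)
    for patient, idx in adata.obs.groupby("patient", observed=True).indices.items():
        n = len(idx)
        if n < min_cells:
            report.removed.append((patient, "low_cells", n, None))
            continue
        t = totals[idx]
        if np.ptp(t) == 0:  # Shapiro undefined on constant input
            p = 0.0
        else:
            p = float(stats.shapiro(t).pvalue)
        if p < normality_alpha:
            report.removed.append((patient, "non_normal", n, p))
        else:
            report.kept.append(patient)
            keep_mask[idx] = True
    if not keep_mask.any():
        raise ValueError(
            f"all patients removed by QC (min_cells={min_cells}, "
            f"normality_alpha={normality_alpha})"
        )
    return adata[keep_mask].copy(), report


def normalize_log(adata: ad.AnnData, target_sum: float = 1e4) -> ad.AnnData:
    """Scale each cell's counts to ``target_sum`` total, then log(1+x)."""
    counts = _counts(adata)
    totals = counts.sum(axis=1)
    scale = np.divide(
        target_sum, totals, out=np.zeros_like(totals, dtype=float), where=totals > 0
    )
    out = adata.copy()
    out.layers["counts"] = counts.copy()
    out.X = np.log1p(counts * scale[:, None])
    out.uns["layer"] = "lognorm"
    return out


def select_hvg(adata: ad.AnnData, n_hvg: int = 12000) -> pd.Index:
    """Top genes by variance of Poisson-standardized, clipped counts.

    Counts are standardized per gene as (x - mean) / sqrt(mean) (the Poisson
    expectation for the SD), clipped at sqrt(n_cells); genes are ranked by the
    variance of the standardized values.  Deterministic, no trend fit.
    """
    counts = _counts(adata)
    n = counts.shape[0]
    if n_hvg > adata.n_vars:
        warnings.warn(
            f"n_hvg={n_hvg} exceeds the {adata.n_vars} available genes; using all"
        )
        n_hvg = adata.n_vars
    mu = counts.mean(axis=0)
    sd = np.sqrt(np.maximum(mu, 1e-12))
    z = np.clip((counts - mu) / sd, -np.sqrt(n), np.sqrt(n))
    score = z.var(axis=0)
    score[mu == 0] = 0.0
    order = np.argsort(-score, kind="stable")
    return adata.var_names[np.sort(order[:n_hvg])]


def scale_genes(adata: ad.AnnData, clip: float = 10.0) -> ad.AnnData:
    """Per-gene z-score of the log layer, clipped at +/- ``clip``."""
    x = np.asarray(adata.X, dtype=float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    out = adata.copy()
    out.X = np.clip((x - mu) / sd, -clip, clip)
    out.uns["layer"] = "scaled"
    return out


def run_pca(
    adata_or_x, n_components: int = 20
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA on the scaled matrix with a deterministic sign convention.

    Each component is flipped so its largest-magnitude gene loading is
    positive.  Returns (cell x component scores, explained variances).
    """
    if isinstance(adata_or_x, ad.AnnData):
        x = np.asarray(adata_or_x.X, dtype=float)
        index = adata_or_x.obs_names
    else:
        x = np.asarray(adata_or_x, dtype=float)
        index = pd.RangeIndex(x.shape[0])
    if n_components > min(x.shape):
        raise ValueError(
            f"n_components={n_components} exceeds min(n_cells, n_genes)={min(x.shape)}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x)
    flip = np.sign(
        pca.components_[np.arange(n_components), np.abs(pca.components_).argmax(axis=1)]
    )
    flip[flip == 0] = 1.0
    scores = scores * flip
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return pd.DataFrame(scores, index=index, columns=cols), pca.explained_variance_


def elbow_select(explained_variance, drop_frac: float = 0.05) -> int:
    """Smallest d with variance(d+1)/variance(1) < drop_frac (advisory only)."""
    ev = np.asarray(explained_variance, dtype=float)
    rel = ev / ev[0]
    below = np.flatnonzero(rel < drop_frac)
    if below.size == 0:
        warnings.warn("variance never drops below drop_frac; returning full length")
        return len(ev)
    return int(below[0])


def cluster_cells(
    scores, k_neighbors: int = 20, resolution: float = 0.8, seed: int = 0
) -> pd.Series:
    """kNN-graph Leiden clustering in PC space; labels 1..K by decreasing size."""
    x = np.asarray(scores, dtype=float)
    n = x.shape[0]
    if k_neighbors >= n:
        raise ValueError(f"k_neighbors={k_neighbors} must be < n_cells={n}")
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(x)
    _, idx = nn.kneighbors(x)
    edges = {(min(i, j), max(i, j)) for i in range(n) for j in idx[i, 1:]}
    g = igraph.Graph(n=n, edges=sorted(edges), directed=False)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=int(seed),
    )
    labels = np.asarray(part.membership)
    sizes = pd.Series(labels).value_counts()
    remap = {old: new + 1 for new, old in enumerate(sizes.index)}
    out = pd.Series([remap[v] for v in labels], name="cluster")
    if isinstance(scores, pd.DataFrame):
        out.index = scores.index
    return out
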