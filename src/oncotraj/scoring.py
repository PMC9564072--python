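"""Signature construction, bulk deconvolution and the patient pseudo-time score.

The headline statistic is the per-patient score S = sum_i P_i * T_i, where P_i
is the deconvolved proportion of cell cluster i in the patient's bulk sample
and T_i is the cluster's mean pseudo-time.  Higher S means a later
developmental state; the score stratifies survival.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import nnls

from .survival import km_estimate, log_rank_test, score_cutpoint_groups  # noqa: F401

__all__ = [
    "SignatureMatrix",
    "DeconvResult",
    "PatientScore",
    "build_signature",
    "deconvolve",
    "ward_group",
    "pseudo_time_score",
    "km_estimate",
    "log_rank_test",
    "score_cutpoint_groups",
    "STAGE_THRESHOLDS",
]

# stage-specific gene-screening thresholds (one-vs-rest p and log2 fold-change)
STAGE_THRESHOLDS = {"III": (0.01, 1.5), "IV": (1e-4, 1.5)}


@dataclass
class SignatureMatrix:
    """Genes x clusters mean log-expression over the selected DE genes."""

    values: pd.DataFrame
    p_thr: float
    lfc_thr: float

    @property
    def genes(self):
        return self.values.index

    @property
    def clusters(self):
        return list(self.values.columns)


@dataclass
class DeconvResult:
    """Per-sample cluster proportions with permutation p and reconstruction r."""

    P: pd.DataFrame  # sample x cluster, rows on the simplex
    pval: pd.Series
    corr: pd.Series
    excluded: pd.Series  # True where pval >= 0.05 or corr <= 0.3

    def retained(self) -> pd.DataFrame:
        return self.P.loc[~self.excluded]


@dataclass
class PatientScore:
    """Per-patient pseudo-time score S and optional group means."""

    S: pd.Series
    group_scores: pd.Series | None = None


def build_signature(
    adata,
    clusters: pd.Series,
    stage: str | None = None,
    p_thr: float | None = None,
    lfc_thr: float | None = None,
) -> SignatureMatrix:
    """One-vs-rest DE screen and per-cluster mean profiles.

    A gene enters the signature when, for any cluster, its Wilcoxon rank-sum p
    is below ``p_thr`` and its log2 fold-change of mean (linear-scale)
    expression exceeds ``lfc_thr``.  ``stage`` fills in the stage-specific
    defaults (III: p<0.01, lfc>1.5; IV: p<1e-4, lfc>1.5).  Expression must be
    log-normalized; the caller restricts cells to the stage's clusters.
    """
    if stage is not None:
        d_p, d_l = STAGE_THRESHOLDS[stage]
        p_thr = d_p if p_thr is None else p_thr
        lfc_thr = d_l if lfc_thr is None else lfc_thr
    if p_thr is None or lfc_thr is None:
        raise ValueError("p_thr and lfc_thr required when stage is not given")

    cl = pd.Series(clusters).reindex(adata.obs_names)
    x = np.asarray(adata.X, dtype=float)
    lin = np.expm1(x)
    keep = np.zeros(adata.n_vars, dtype=bool)
    uniq = sorted(cl.dropna().unique())
    if len(uniq) < 2:
        raise ValueError("need at least two clusters to build a signature")
    for c in uniq:
        mask = (cl == c).to_numpy()
        pv = stats.mannwhitneyu(
            x[mask], x[~mask], axis=0, alternative="two-sided", method="asymptotic"
        ).pvalue
        lfc = np.log2(lin[mask].mean(axis=0) + 1e-9) - np.log2(
            lin[~mask].mean(axis=0) + 1e-9
        )
        keep |= (pv < p_thr) & (lfc > lfc_thr)
    if not keep.any():
        raise ValueError(
            f"no genes pass the signature screen (p<{p_thr}, log2fc>{lfc_thr})"
        )
    genes = adata.var_names[keep]
    sig = pd.DataFrame(
        {c: x[(cl == c).to_numpy()][:, keep].mean(axis=0) for c in uniq}, index=genes
    )
    sig = sig.loc[(sig != 0).any(axis=1)]
    return SignatureMatrix(values=sig, p_thr=p_thr, lfc_thr=lfc_thr)


def _fit_weights(a: np.ndarray, y: np.ndarray, method: str) -> np.ndarray:
    if method == "nnls":
        w, _ = nnls(a, y)
        return w
    if method == "nusvr":
        from sklearn.svm import NuSVR

        best, best_rmse = None, np.inf
        for nu in (0.25, 0.5, 0.75):
            model = NuSVR(kernel="linear", nu=nu, C=1.0)
            model.fit(a, y)
            w = np.clip(model.coef_.ravel(), 0.0, None)
            rmse = float(np.sqrt(np.mean((a @ w - y) ** 2)))
            if rmse < best_rmse:
                best, best_rmse = w, rmse
        return best
    raise ValueError(f"unknown method {method!r}")


def deconvolve(
    bulk: pd.DataFrame,
    sig: SignatureMatrix,
    method: str = "nnls",
    n_perm: int = 200,
    seed: int = 0,
) -> DeconvResult:
    """Estimate cluster proportions of each bulk sample from the signature.

    Non-negative weights (NNLS by default, linear nu-SVR optional) are
    renormalized to the simplex.  Per sample, ``corr`` is the Pearson
    correlation between the reconstruction and the observed profile over the
    signature genes, and ``pval`` compares it against refits to gene-permuted
    profiles.  Samples failing p < 0.05 or corr > 0.3 are flagged excluded.
    """
    shared = sig.genes.intersection(bulk.index)
    if len(shared) < 2 * len(sig.clusters):
        raise ValueError(
            f"only {len(shared)} signature genes shared with the bulk matrix; "
            f"need >= {2 * len(sig.clusters)}"
        )
    a = sig.values.loc[shared].to_numpy()
    if np.linalg.matrix_rank(a) < a.shape[1]:
        warnings.warn("signature matrix is rank-deficient; proportions may be unstable")
    rng = np.random.default_rng(seed)
    perms = [rng.permutation(len(shared)) for _ in range(n_perm)]

    rows, pvals, corrs = [], [], []
    for s in bulk.columns:
        y = bulk.loc[shared, s].to_numpy(dtype=float)
        w = _fit_weights(a, y, method)
        recon = a @ w
        r = _pearson(recon, y)
        null = np.array(
            [_pearson(a @ _fit_weights(a, y[pm], method), y[pm]) for pm in perms]
        )
        p = (1.0 + np.count_nonzero(null >= r)) / (n_perm + 1.0)
        total = w.sum()
        rows.append(w / total if total > 0 else np.full(len(w), 1.0 / len(w)))
        pvals.append(p)
        corrs.append(r)
    P = pd.DataFrame(rows, index=bulk.columns, columns=sig.clusters)
    pval = pd.Series(pvals, index=bulk.columns, name="pval")
    corr = pd.Series(corrs, index=bulk.columns, name="corr")
    excluded = ~((pval < 0.05) & (corr > 0.3))
    excluded.name = "excluded"
    return DeconvResult(P=P, pval=pval, corr=corr, excluded=excluded)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def ward_group(P: pd.DataFrame, k: int = 2) -> pd.Series:
    """Ward-linkage hierarchical clustering of proportion rows, cut at k."""
    if k >= len(P):
        return pd.Series(range(1, len(P) + 1), index=P.index, name="group")
    lk = linkage(P.to_numpy(), method="ward", metric="euclidean")
    return pd.Series(
        fcluster(lk, t=k, criterion="maxclust"), index=P.index, name="group"
    )


def pseudo_time_score(
    P: pd.DataFrame, T: pd.Series, groups: pd.Series | None = None
) -> PatientScore:
    """S = sum_i P_i * T_i per patient; optional group-level mean scores."""
    missing = [c for c in P.columns if c not in T.index]
    if missing:
        raise ValueError(f"clusters missing from T: {missing}")
    s = pd.Series(
        P.to_numpy() @ T.loc[P.columns].to_numpy(dtype=float), index=P.index, name="S"
    )
    group_scores = None
    if groups is not None:
        g = pd.Series(groups).reindex(P.index)
        group_scores = s.groupby(g).mean()
        group_scores.name = "group_score"
    return PatientScore(S=s, group_scores=group_scores)
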