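"""Branch-dependent expression testing at the branch point.

The test is BEAM-style: cells before the branch are duplicated into both
branches, a full model fits one smooth pseudo-time trend per branch and a
reduced model fits a shared trend, and the branch effect is assessed by a
likelihood-ratio test.  Significant genes are split into two co-expression
sets by Ward clustering of their fitted branch curves, and gene sets are
annotated by hypergeometric enrichment against user-supplied GMT collections.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from statsmodels.stats.multitest import multipletests

from .sim import PATH_I, PATH_II, PRE

__all__ = [
    "natural_spline_basis",
    "beam_test",
    "filter_branch_genes",
    "cluster_branch_genes",
    "enrich",
]


def natural_spline_basis(x, df: int = 3, knots=None):
    """Natural cubic spline basis (no intercept column), R ``ns()``-style.

    ``df`` basis functions; interior knots at quantiles k/df of ``x`` unless
    ``knots`` (full ordered knot vector, boundaries included) is given.
    Returns ``(basis, knots)`` so a fitted basis can be re-evaluated on a grid.
    """
    x = np.asarray(x, dtype=float)
    if knots is None:
        qs = np.linspace(0.0, 1.0, df + 1)
        knots = np.unique(np.quantile(x, qs))
        if len(knots) < 3:  # degenerate spread: fall back to a linear basis
            return x[:, None].copy(), knots
    knots = np.asarray(knots, dtype=float)
    k_last = knots[-1]

    def d(j):
        num = np.clip(x - knots[j], 0, None) ** 3 - np.clip(x - k_last, 0, None) ** 3
        return num / (k_last - knots[j])

    cols = [x]
    d_penult = d(len(knots) - 2)
    for j in range(len(knots) - 2):
        cols.append(d(j) - d_penult)
    return np.column_stack(cols), knots


def _branch_design(traj, cells, spline_df: int):
    """Duplicated PRE design: rows, branch indicator, pseudo-time, knots."""
    branch = traj.branch.loc[cells]
    t = traj.pseudotime.loc[cells]
    pre = branch == PRE
    p1 = branch == PATH_I
    p2 = branch == PATH_II
    for name, mask in ((PATH_I, pre | p1), (PATH_II, pre | p2)):
        if int(mask.sum()) < spline_df + 2:
            raise ValueError(
                f"branch {name} has {int(mask.sum())} cells; "
                f"needs at least spline_df+2 = {spline_df + 2}"
            )
    rows = np.concatenate([np.flatnonzero(pre | p1), np.flatnonzero(pre | p2)])
    ind = np.concatenate(
        [np.zeros(int((pre | p1).sum())), np.ones(int((pre | p2).sum()))]
    )
    tt = t.to_numpy()[rows]
    basis, knots = natural_spline_basis(tt, df=spline_df)
    return rows, ind, tt, basis, knots


def _rss(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return np.einsum("ij,ij->j", resid, resid), beta


def beam_test(
    adata,
    traj,
    spline_df: int = 3,
    family: str = "gaussian",
    genes=None,
) -> pd.DataFrame:
    """Likelihood-ratio test for branch-dependent expression along pseudo-time.

    Full model: expression ~ spline(t) x branch; reduced: expression ~
    spline(t); cells before the branch enter both branches.  The Gaussian
    family (default) runs vectorized over genes on log-normalized values; the
    negative-binomial family loops genes over GLM fits on counts.
    Returns gene, llr, df, p, q (BH) and expressed_frac.
    """
    if not (traj.branch == PATH_II).any() or not (traj.branch == PATH_I).any():
        raise ValueError("trajectory must have two populated paths")
    cells = adata.obs_names.intersection(traj.branch.index)
    rows, ind, tt, basis, _ = _branch_design(traj, cells, spline_df)
    x = np.asarray(adata[cells].X, dtype=float)
    if genes is None:
        genes = list(adata.var_names)
    gidx = [adata.var_names.get_loc(g) for g in genes]
    y_cells = x[:, gidx]
    y = y_cells[rows]

    ones = np.ones((len(rows), 1))
    x_red = np.hstack([ones, basis])
    x_full = np.hstack([x_red, ind[:, None], basis * ind[:, None]])
    df_diff = x_full.shape[1] - x_red.shape[1]

    if family == "gaussian":
        rss_full, _ = _rss(x_full, y)
        rss_red, _ = _rss(x_red, y)
        n = len(rows)
        rss_full = np.maximum(rss_full, 1e-300)
        llr = n * np.log(np.maximum(rss_red, rss_full) / rss_full)
    elif family == "negative_binomial":
        import statsmodels.api as sm

        llr = np.empty(len(genes))
        for j in range(len(genes)):
            yj = y[:, j]
            mu, var = yj.mean(), yj.var()
            alpha = max((var - mu) / max(mu**2, 1e-12), 0.01)
            fam = sm.families.NegativeBinomial(alpha=alpha)
            full = sm.GLM(yj, x_full, family=fam).fit()
            red = sm.GLM(yj, x_red, family=fam).fit()
            llr[j] = 2.0 * (full.llf - red.llf)
        llr = np.maximum(llr, 0.0)
    else:
        raise ValueError(f"unknown family {family!r}")

    p = stats.chi2.sf(llr, df_diff)
    q = multipletests(p, method="fdr_bh")[1]
    expressed = (y_cells > 0).mean(axis=0)
    return pd.DataFrame(
        {
            "gene": genes,
            "llr": llr,
            "df": df_diff,
            "p": p,
            "q": q,
            "expressed_frac": expressed,
        }
    )


def filter_branch_genes(
    results: pd.DataFrame, q_max: float = 1e-8, min_expressed_frac: float = 0.20
) -> list:
    """Genes with q < q_max and expressed in more than ``min_expressed_frac`` of cells."""
    if len(results) == 0:
        return []
    keep = (results["q"] < q_max) & (results["expressed_frac"] > min_expressed_frac)
    return results.loc[keep, "gene"].tolist()


def cluster_branch_genes(
    genes,
    adata,
    traj,
    k: int = 2,
    spline_df: int = 3,
    n_grid: int = 50,
) -> tuple[pd.Series, pd.DataFrame]:
    """Split branch genes into co-expression sets by Ward clustering.

    Each gene's full-model fit is evaluated on a fixed pseudo-time grid for
    both branches (Path I reversed, then Path II -> a branch-point-centred
    curve), rows are standardized to mean 0 / SD 1, and Ward (Euclidean)
    hierarchical clustering is cut at ``k``.
    """
    genes = list(genes)
    cells = adata.obs_names.intersection(traj.branch.index)
    rows, ind, tt, basis, knots = _branch_design(traj, cells, spline_df)
    x = np.asarray(adata[cells].X, dtype=float)
    gidx = [adata.var_names.get_loc(g) for g in genes]
    y = x[rows][:, gidx]

    ones = np.ones((len(rows), 1))
    x_full = np.hstack([ones, basis, ind[:, None], basis * ind[:, None]])
    _, beta = _rss(x_full, y)

    grid = np.linspace(tt.min(), tt.max(), n_grid)
    gbasis, _ = natural_spline_basis(grid, df=spline_df, knots=knots)
    g1 = np.hstack(
        [np.ones((n_grid, 1)), gbasis, np.zeros((n_grid, 1)), np.zeros_like(gbasis)]
    )
    g2 = np.hstack([np.ones((n_grid, 1)), gbasis, np.ones((n_grid, 1)), gbasis])
    curves = np.vstack([(g1 @ beta)[::-1], g2 @ beta]).T  # genes x 2*n_grid

    mu = curves.mean(axis=1, keepdims=True)
    sd = curves.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (curves - mu) / sd
    cols = [f"I_{i}" for i in range(n_grid)][::-1] + [f"II_{i}" for i in range(n_grid)]
    mat = pd.DataFrame(z, index=genes, columns=cols)
    if k == 1 or len(genes) < 2:
        labels = pd.Series(1, index=genes, name="gene_set")
    else:
        lk = linkage(z, method="ward", metric="euclidean")
        labels = pd.Series(
            fcluster(lk, t=k, criterion="maxclust"), index=genes, name="gene_set"
        )
    return labels, mat


def _storey_pi0(p: np.ndarray, lam: float = 0.5) -> float:
    return float(min(1.0, np.mean(p > lam) / (1.0 - lam)))


def enrich(gene_set, universe, collections: dict) -> pd.DataFrame:
    """Hypergeometric upper-tail enrichment of ``gene_set`` against GMT terms.

    ``collections`` maps term -> gene iterable.  Terms with no universe overlap
    are skipped.  Reports raw p, BH ``p_adjust`` and a Storey-type ``q``
    (single-lambda pi0 estimate), plus a ``significant`` flag at
    p_adjust < 0.05 and q < 0.05.
    """
    gene_set = set(gene_set)
    universe = set(universe)
    if not gene_set <= universe:
        raise ValueError("gene_set must be contained in universe")
    n_univ, n_draw = len(universe), len(gene_set)
    rows = []
    for term, members in collections.items():
        in_univ = set(members) & universe
        if not in_univ:
            continue
        k = len(in_univ & gene_set)
        p = stats.hypergeom.sf(k - 1, n_univ, len(in_univ), n_draw)
        rows.append((term, k, len(in_univ), float(min(p, 1.0))))
    out = pd.DataFrame(rows, columns=["term", "overlap", "term_size", "p"])
    if len(out):
        out["p_adjust"] = multipletests(out["p"], method="fdr_bh")[1]
        out["q"] = np.minimum(_storey_pi0(out["p"].to_numpy()) * out["p_adjust"], 1.0)
        out["significant"] = (out["p_adjust"] < 0.05) & (out["q"] < 0.05)
    return out.sort_values("p", ignore_index=True) if len(out) else out
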