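"""Plain-text readers and writers for the pipeline's file interfaces.

All formats are TSV/MTX/JSON/GMT; single-cell matrices round-trip through
MatrixMarket plus gene/barcode TSVs with a cell-metadata TSV alongside.
"""

from __future__ import annotations

import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = [
    "write_cell_matrix",
    "read_cell_matrix",
    "read_gmt",
    "write_gmt",
    "write_ground_truth",
]


def write_cell_matrix(adata: ad.AnnData, outdir) -> None:
    """MTX (genes x cells) + genes.tsv + barcodes.tsv + cell_meta.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts = adata.layers.get("counts", adata.X)
    spio.mmwrite(outdir / "matrix.mtx", sparse.csr_matrix(np.asarray(counts).T))
    pd.Series(adata.var_names).to_csv(
        outdir / "genes.tsv", sep="\t", index=False, header=False
    )
    pd.Series(adata.obs_names).to_csv(
        outdir / "barcodes.tsv", sep="\t", index=False, header=False
    )
    meta = adata.obs.reset_index(names="cell_id")
    meta.to_csv(outdir / "cell_meta.tsv", sep="\t", index=False)


def read_cell_matrix(indir) -> ad.AnnData:
    indir = Path(indir)
    m = spio.mmread(indir / "matrix.mtx").toarray().T  # back to cells x genes
    genes = pd.read_csv(indir / "genes.tsv", sep="\t", header=None)[0]
    cells = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0]
    meta = pd.read_csv(indir / "cell_meta.tsv", sep="\t").set_index("cell_id")
    adata = ad.AnnData(
        X=m.astype(float),
        obs=meta.loc[cells],
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    adata.layers["counts"] = adata.X.copy()
    adata.uns["layer"] = "counts"
    return adata


def read_gmt(path) -> dict:
    """GMT gene-set file -> {term: set of genes}."""
    out = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                out[parts[0]] = set(g for g in parts[2:] if g)
    return out


def write_gmt(collections: dict, path) -> None:
    with open(path, "w") as fh:
        for term, genes in collections.items():
            fh.write("\t".join([term, term] + sorted(genes)) + "\n")


def write_ground_truth(truth, path) -> None:
    """Ground truth as JSON (series keyed by id; frames as column dicts)."""
    payload = {
        "cluster": truth.cluster.to_dict(),
        "pseudotime": truth.pseudotime.to_dict(),
        "branch": truth.branch.to_dict(),
        "stage": truth.stage.to_dict(),
        "marker_genes": truth.marker_genes,
        "branch_genes": truth.branch_genes.to_dict(orient="list"),
        "cluster_path": {str(k): v for k, v in truth.cluster_path.items()},
        "proportions": None
        if truth.proportions is None
        else truth.proportions.to_dict(orient="index"),
        "effective_drugs": truth.effective_drugs,
        "hub_gene": truth.hub_gene,
        "rl_planted": truth.rl_planted,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, default=str)
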