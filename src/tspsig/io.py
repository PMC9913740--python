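"""Reading and writing the pipeline's plain-text formats.

Counts: a 10x-style directory (matrix.mtx + barcodes.tsv + features.tsv,
features carrying gene id, symbol and biotype) or a dense CSV with cells
in rows.  Expression, centroid, clinical and IC50 tables are CSV;
signatures are JSON (see :class:`~tspsig.cm1_signatures.SignatureSet`).
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import anndata as ad
from scipy import io as scio
from scipy import sparse


def read_counts(path: Union[str, Path], annotation: Optional[Union[str, Path]] = None) -> ad.AnnData:
    """Load a count matrix from a 10x-style directory or a dense CSV (cells x genes).

    ``annotation`` optionally points to a CSV with columns ``cell_id`` and
    ``label``, stored as ``obs["cell_label"]``.
    """
    p = Path(path)
    if p.is_dir():
        mtx = scio.mmread(p / "matrix.mtx")  # genes x cells, MatrixMarket convention
        barcodes = pd.read_csv(p / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
        feats = pd.read_csv(p / "features.tsv", sep="\t", header=None)
        X = np.asarray(sparse.csr_matrix(mtx).T.todense())
        var = pd.DataFrame(index=feats[0].astype(str))
        if feats.shape[1] > 1:
            var["symbol"] = feats[1].to_numpy()
        var["biotype"] = feats[2].to_numpy() if feats.shape[1] > 2 else "protein_coding"
        adata = ad.AnnData(X=X.astype(np.int64), obs=pd.DataFrame(index=barcodes), var=var)
    else:
        df = pd.read_csv(p, index_col=0)
        adata = ad.AnnData(
            X=df.to_numpy(dtype=np.int64),
            obs=pd.DataFrame(index=df.index.astype(str)),
            var=pd.DataFrame({"biotype": "protein_coding"}, index=df.columns.astype(str)),
        )
    if annotation is not None:
        ann = pd.read_csv(annotation).set_index("cell_id")["label"]
        adata.obs["cell_label"] = ann.reindex(adata.obs_names).to_numpy()
    return adata


def write_counts(adata: ad.AnnData, outdir: Union[str, Path]) -> None:
    """Write counts as matrix.mtx + barcodes.tsv + features.tsv."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    X = adata.X
    if not sparse.issparse(X):
        X = sparse.csr_matrix(X)
    scio.mmwrite(str(out / "matrix.mtx"), X.T.astype(int))
    pd.Series(adata.obs_names).to_csv(out / "barcodes.tsv", sep="\t", header=False, index=False)
    feats = pd.DataFrame(
        {
            0: adata.var_names,
            1: adata.var["symbol"] if "symbol" in adata.var else adata.var_names,
            2: adata.var["biotype"] if "biotype" in adata.var else "protein_coding",
        }
    )
    feats.to_csv(out / "features.tsv", sep="\t", header=False, index=False)


def read_expression(path: Union[str, Path]) -> pd.DataFrame:
    """Samples/cells x genes CSV with the identifier in the first column."""
    return pd.read_csv(path, index_col=0)


def write_expression(adata_or_df, path: Union[str, Path]) -> None:
    if isinstance(adata_or_df, ad.AnnData):
        df = pd.DataFrame(
            np.asarray(adata_or_df.X), index=adata_or_df.obs_names,
            columns=adata_or_df.var_names,
        )
    else:
        df = adata_or_df
    df.to_csv(path)


def read_centroids(path: Union[str, Path]) -> pd.DataFrame:
    """Genes x subtypes CSV, first column gene_id."""
    return pd.read_csv(path, index_col=0)


def read_clinical(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)
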