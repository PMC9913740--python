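"""Nearest-centroid subtype assignment by correlation.

Each unit (cell, bulk sample or cell line) is correlated with every
subtype centroid over the genes shared between the expression matrix and
the centroid panel; the unit is assigned to the subtype with the highest
positive correlation, or left "unassigned" when no correlation is
positive.  This is the correlation-to-centroid rule of the TNBCtype-4
taxonomy (BL1, BL2, LAR, M) with a user-supplied centroid matrix.
"""

from __future__ import annotations

import warnings
from typing import Union

import numpy as np
import pandas as pd
import anndata as ad
from scipy.stats import rankdata

UNASSIGNED = "unassigned"
DEFAULT_SUBTYPES = ("BL1", "BL2", "LAR", "M")


def _expr_frame(expr: Union[ad.AnnData, pd.DataFrame]) -> pd.DataFrame:
    if isinstance(expr, ad.AnnData):
        X = expr.X
        if not isinstance(X, np.ndarray):
            X = np.asarray(X.todense())
        return pd.DataFrame(X, index=expr.obs_names, columns=expr.var_names)
    return expr


def classify(
    expr: Union[ad.AnnData, pd.DataFrame],
    centroids: pd.DataFrame,
    method: str = "pearson",
    min_shared_genes: int = 20,
) -> pd.DataFrame:
    """Assign units to subtypes by highest positive centroid correlation.

    Parameters
    ----------
    expr
        Units x genes expression (log scale for Pearson).
    centroids
        Genes x subtypes centroid matrix; column order defines the
        tie-break order.
    method
        "pearson" or "spearman".
    min_shared_genes
        Minimum gene overlap between ``expr`` and ``centroids``.

    Returns
    -------
    DataFrame indexed by unit id with columns ``label``, ``best_corr``,
    ``undefined_corr`` and one ``corr_<subtype>`` column per centroid.
    Units with no positive correlation (or zero-variance expression) get
    label "unassigned".
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    E = _expr_frame(expr)
    shared = E.columns.intersection(centroids.index)
    if len(shared) < min_shared_genes:
        raise ValueError(
            f"only {len(shared)} genes shared with centroids "
            f"(min_shared_genes={min_shared_genes})"
        )
    X = E[shared].to_numpy(dtype=float)  # units x g
    C = centroids.loc[shared].to_numpy(dtype=float)  # g x k
    if np.ptp(C, axis=0).min() == 0:
        bad = centroids.columns[np.ptp(C, axis=0) == 0].tolist()
        raise ValueError(f"constant centroid column(s) over shared genes: {bad}")
    if method == "spearman":
        X = rankdata(X, axis=1)
        C = rankdata(C, axis=0)

    Xc = X - X.mean(axis=1, keepdims=True)
    Cc = C - C.mean(axis=0, keepdims=True)
    xn = np.linalg.norm(Xc, axis=1)
    cn = np.linalg.norm(Cc, axis=0)
    undefined = xn == 0
    xn_safe = np.where(undefined, 1.0, xn)
    corr = (Xc @ Cc) / (xn_safe[:, None] * cn[None, :])
    corr[undefined] = np.nan

    subtypes = list(centroids.columns)
    labels = np.full(len(X), UNASSIGNED, dtype=object)
    best = np.full(len(X), np.nan)
    with np.errstate(invalid="ignore"):
        arg = np.nanargmax(np.where(np.isnan(corr), -np.inf, corr), axis=1)
    n_ties = 0
    for i in range(len(X)):
        if undefined[i]:
            continue
        row = corr[i]
        m = row[arg[i]]
        best[i] = m
        if m > 0:
            labels[i] = subtypes[arg[i]]
            if (row == m).sum() > 1:
                n_ties += 1
    if n_ties:
        warnings.warn(
            f"{n_ties} unit(s) had tied best correlations; "
            "first subtype in column order assigned",
            RuntimeWarning,
        )
    if undefined.any():
        warnings.warn(
            f"{int(undefined.sum())} unit(s) with zero-variance expression "
            "left unassigned (undefined correlation)",
            RuntimeWarning,
        )
    out = pd.DataFrame(
        {"label": labels, "best_corr": best, "undefined_corr": undefined},
        index=E.index,
    )
    for j, s in enumerate(subtypes):
        out[f"corr_{s}"] = corr[:, j]
    out.index.name = "unit_id"
    return out
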