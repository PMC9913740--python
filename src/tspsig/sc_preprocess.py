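"""Quality filtering and size-factor normalization of single-cell UMI counts.

The count matrix lives in an :class:`anndata.AnnData` with cells as
observations and genes as variables.  Gene biotypes are expected in
``adata.var["biotype"]`` and optional cell annotations (e.g.
``"Cancer Epithelial"``) in ``adata.obs["cell_label"]``.

Normalization follows the pooling-deconvolution idea: cells are summed
into overlapping pools, each pooled profile is scaled against the average
cell profile, and the resulting overdetermined linear system in the
per-cell size factors is solved by least squares.  Pooling makes the
median-ratio step robust to the zero inflation of droplet UMI data that
defeats per-cell median ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import anndata as ad
from scipy import sparse
from scipy.sparse.linalg import lsmr

DEFAULT_POOL_SIZES: tuple[int, ...] = (21, 41, 61, 81, 101)
DEFAULT_EXCLUDE_PREFIXES: tuple[str, ...] = ("MT-", "RPL", "RPS")


@dataclass
class SizeFactors:
    """Per-cell scaling factors, rescaled to mean 1.

    ``library_fallback`` is True when the deconvolution system produced a
    non-positive factor and library-size factors were returned instead.
    """

    factor: pd.Series
    library_fallback: bool = False

    def __post_init__(self) -> None:
        if (self.factor <= 0).any():
            raise ValueError("size factors must be strictly positive")

    @property
    def values(self) -> np.ndarray:
        return self.factor.to_numpy(dtype=float)


def _dense_counts(adata: ad.AnnData) -> np.ndarray:
    X = adata.X
    if sparse.issparse(X):
        X = X.toarray()
    return np.asarray(X, dtype=float)


def validate_counts(adata: ad.AnnData) -> None:
    """Check the count-matrix invariants: unique ids, integral non-negative counts."""
    if adata.obs_names.duplicated().any():
        raise ValueError("duplicate cell identifiers")
    if adata.var_names.duplicated().any():
        raise ValueError("duplicate gene identifiers")
    X = _dense_counts(adata)
    if (X < 0).any():
        raise ValueError("counts must be non-negative")
    if not np.allclose(X, np.round(X)):
        raise ValueError("counts must be integral")


def filter_genes(
    adata: ad.AnnData,
    keep_biotypes: Optional[Iterable[str]] = ("protein_coding",),
    exclude_prefixes: Iterable[str] = DEFAULT_EXCLUDE_PREFIXES,
    min_cells: int = 3,
) -> ad.AnnData:
    """Retain genes by biotype, symbol prefix and detection frequency.

    A gene is kept when its biotype is in ``keep_biotypes`` (skipped when
    None), its identifier does not start with any prefix in
    ``exclude_prefixes`` (mitochondrial/ribosomal by default), and it is
    detected (count > 0) in at least ``min_cells`` cells.  Cells are
    untouched.
    """
    if min_cells < 0:
        raise ValueError("min_cells must be >= 0")
    mask = np.ones(adata.n_vars, dtype=bool)
    if keep_biotypes is not None:
        if "biotype" not in adata.var:
            raise KeyError("gene biotype column 'biotype' missing from adata.var")
        mask &= adata.var["biotype"].isin(set(keep_biotypes)).to_numpy()
    prefixes = tuple(exclude_prefixes)
    if prefixes:
        names = adata.var_names.to_numpy(dtype=object)
        mask &= ~np.array([str(g).startswith(prefixes) for g in names])
    detected = (_dense_counts(adata) > 0).sum(axis=0)
    mask &= detected >= min_cells
    if not mask.any():
        raise ValueError("no genes pass filters")
    return adata[:, mask].copy()


def filter_cells(
    adata: ad.AnnData,
    min_genes: int = 200,
    keep_label: Optional[str] = None,
) -> ad.AnnData:
    """Retain cells with >= ``min_genes`` detected genes and, optionally, a given label."""
    if min_genes < 0:
        raise ValueError("min_genes must be >= 0")
    mask = (_dense_counts(adata) > 0).sum(axis=1) >= min_genes
    if keep_label is not None:
        if "cell_label" not in adata.obs:
            raise KeyError("cell annotation column 'cell_label' missing from adata.obs")
        mask &= (adata.obs["cell_label"] == keep_label).to_numpy()
    if not mask.any():
        raise ValueError("no cells pass filters")
    return adata[mask].copy()


def compute_size_factors(
    adata: ad.AnnData,
    pool_sizes: Sequence[int] = DEFAULT_POOL_SIZES,
    cell_weight: float = 0.01,
) -> SizeFactors:
    """Pooling-deconvolution size factors.

    Cells are placed on a ring ordered by library size.  For each pool size
    ``s`` and each ring position, the ``s`` consecutive cells are summed and
    the pooled profile is compared with the average cell profile by a
    median ratio across genes; that ratio estimates the sum of the member
    cells' factors, one linear equation per pool.  Low-weight per-cell
    library-size equations (weight ``cell_weight``) anchor the scale of the
    least-squares solution.  Factors are rescaled to mean 1.

    If any solved factor is non-positive the estimate is abandoned and
    library-size factors are returned with ``library_fallback=True``.
    """
    if not pool_sizes:
        raise ValueError("at least one pool size required")
    if any(s < 2 for s in pool_sizes):
        raise ValueError("every pool size must be >= 2")
    n = adata.n_obs
    if n < min(pool_sizes):
        raise ValueError(
            f"fewer cells ({n}) than smallest pool size ({min(pool_sizes)})"
        )
    sizes = sorted({min(int(s), n) for s in pool_sizes})

    X = _dense_counts(adata)
    lib = X.sum(axis=1)
    if (lib <= 0).any():
        raise ValueError("cells with zero total count; filter cells first")
    ref = X.mean(axis=0)
    expressed = ref > 0
    Xe = X[:, expressed]
    refe = ref[expressed]

    # ring sorted by library size, ties broken by cell id so the result is
    # invariant to the input's cell ordering
    order = np.lexsort((adata.obs_names.to_numpy(), lib))
    Xo = Xe[order]
    # prefix sums over the doubled ring give every wrap-around pool sum
    cs = np.vstack([np.zeros((1, Xo.shape[1])), np.cumsum(np.vstack([Xo, Xo]), axis=0)])

    rows, cols, vals, b = [], [], [], []
    row = 0
    for s in sizes:
        starts = np.arange(n)
        pooled = cs[starts + s] - cs[starts]  # n pools x genes
        theta = np.median(pooled / refe, axis=1)
        member = (starts[:, None] + np.arange(s)[None, :]) % n
        cols.append(order[member].ravel())
        rows.append(np.repeat(starts + row, s))
        vals.append(np.ones(n * s))
        b.append(theta)
        row += n
    # anchor equations: factor_c ~ library-size factor, tiny weight
    rows.append(np.arange(row, row + n))
    cols.append(np.arange(n))
    vals.append(np.full(n, cell_weight))
    b.append(cell_weight * lib / lib.mean())
    row += n

    A = sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(row, n),
    )
    rhs = np.concatenate(b)
    sol = lsmr(A, rhs, atol=1e-12, btol=1e-12)[0]

    fallback = False
    if (sol <= 0).any():
        warnings.warn(
            "deconvolution produced non-positive factors; "
            "falling back to library-size factors",
            RuntimeWarning,
        )
        sol = lib.copy()
        fallback = True
    sol = sol / sol.mean()
    return SizeFactors(pd.Series(sol, index=adata.obs_names, name="factor"), fallback)


def normalize(adata: ad.AnnData, factors: SizeFactors) -> ad.AnnData:
    """Scale counts by size factors and log-transform: log2(count/factor + 1)."""
    f = factors.factor.reindex(adata.obs_names)
    if f.isna().any():
        raise ValueError("size factors missing for some cells")
    if (f <= 0).any():
        raise ValueError("non-positive size factor")
    X = _dense_counts(adata)
    expr = np.log2(X / f.to_numpy()[:, None] + 1.0)
    out = ad.AnnData(
        X=expr, obs=adata.obs.copy(), var=adata.var.copy(), uns=dict(adata.uns)
    )
    out.uns["normalization"] = "log2(count/size_factor + 1)"
    return out


def preprocess(
    adata: ad.AnnData,
    keep_label: Optional[str] = None,
    keep_biotypes: Optional[Iterable[str]] = ("protein_coding",),
    exclude_prefixes: Iterable[str] = DEFAULT_EXCLUDE_PREFIXES,
    min_genes: int = 200,
    min_cells: int = 3,
    pool_sizes: Sequence[int] = DEFAULT_POOL_SIZES,
) -> tuple[ad.AnnData, SizeFactors, ad.AnnData]:
    """Full QC + normalization: returns (filtered counts, size factors, expression)."""
    filtered = filter_genes(adata, keep_biotypes, exclude_prefixes, min_cells)
    filtered = filter_cells(filtered, min_genes, keep_label)
    factors = compute_size_factors(filtered, pool_sizes)
    return filtered, factors, normalize(filtered, factors)
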