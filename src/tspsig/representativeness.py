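"""Are the selected markers representative? Expression, entropy, co-expression.

Signature genes are compared against the background (all retained genes
minus all signature genes) on three per-gene summaries: mean expression,
histogram plug-in Shannon entropy of the expression distribution, and
mean absolute pairwise correlation with the other genes of the set.
Group differences are tested with a two-sided Wilcoxon rank-sum test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import anndata as ad
from scipy import stats

from .cm1_signatures import SignatureSet
from .subtype_classifier import _expr_frame


def gene_entropy(values: Sequence[float], n_bins: int = 10) -> float:
    """Plug-in Shannon entropy (bits) of an equal-width histogram.

    Bins span [min, max] of the vector; a constant vector occupies a
    single bin and has entropy 0.  The estimate never exceeds
    log2(n_bins).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise ValueError("empty vector")
    if not np.isfinite(v).all():
        raise ValueError("non-finite values")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if v.min() == v.max():
        return 0.0
    counts, _ = np.histogram(v, bins=n_bins, range=(v.min(), v.max()))
    p = counts[counts > 0] / v.size
    return float(-(p * np.log2(p)).sum())


def intergene_correlation(
    expr: Union[ad.AnnData, pd.DataFrame],
    gene_set: Sequence[str],
    method: str = "spearman",
    max_pairs: Optional[int] = None,
    seed: int = 0,
) -> pd.Series:
    """Per-gene mean absolute pairwise correlation within ``gene_set``.

    When the number of pairs exceeds ``max_pairs`` a seeded uniform
    subsample of pairs is used.  Constant genes (undefined correlation)
    are excluded with a warning.
    """
    genes = list(dict.fromkeys(gene_set))
    if len(genes) < 2:
        raise ValueError("gene_set must contain >= 2 genes")
    E = _expr_frame(expr)
    missing = [g for g in genes if g not in E.columns]
    if missing:
        raise KeyError(f"genes absent from expression matrix: {missing[:5]}")
    X = E[genes]
    const = X.std(ddof=0) == 0
    if const.any():
        warnings.warn(
            f"excluded {int(const.sum())} constant gene(s) with undefined correlation",
            RuntimeWarning,
        )
        genes = [g for g in genes if not const[g]]
        if len(genes) < 2:
            raise ValueError("fewer than 2 non-constant genes")
        X = E[genes]

    pairs = list(combinations(range(len(genes)), 2))
    if max_pairs is not None and len(pairs) > max_pairs:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[i] for i in idx]

    M = X.to_numpy(dtype=float)
    if method == "spearman":
        M = stats.rankdata(M, axis=0)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    C = np.corrcoef(M, rowvar=False)

    sums = np.zeros(len(genes))
    counts = np.zeros(len(genes))
    for i, j in pairs:
        a = abs(C[i, j])
        sums[i] += a
        sums[j] += a
        counts[i] += 1
        counts[j] += 1
    with np.errstate(invalid="ignore"):
        mean_abs = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    if (counts == 0).any():
        warnings.warn("some genes had no sampled pairs; NaN returned", RuntimeWarning)
    return pd.Series(mean_abs, index=genes, name="intergene_corr")


@dataclass
class ComparisonResult:
    """Two-sided rank-sum comparison of signature vs background values."""

    metric_name: str
    statistic: float
    p_value: float
    n_signature: int
    n_background: int
    signature_median: float
    background_median: float


def compare_to_background(
    sig: Sequence[float], bg: Sequence[float], metric_name: str = "metric"
) -> ComparisonResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test of sig vs bg.

    Exact enumeration for small tie-free samples, normal approximation
    with tie correction otherwise (scipy's "auto" policy).  If every value
    in both groups is identical the test is vacuous and p = 1 by
    convention.
    """
    a = np.asarray(sig, dtype=float)
    b = np.asarray(bg, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.unique(np.concatenate([a, b])).size == 1:
        return ComparisonResult(
            metric_name, a.size * b.size / 2.0, 1.0, a.size, b.size,
            float(np.median(a)), float(np.median(b)),
        )
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return ComparisonResult(
        metric_name,
        float(res.statistic),
        float(min(res.pvalue, 1.0)),
        a.size,
        b.size,
        float(np.median(a)),
        float(np.median(b)),
    )


def representativeness_report(
    expr: Union[ad.AnnData, pd.DataFrame],
    signatures: SignatureSet,
    n_bins: int = 10,
    method: str = "spearman",
    seed: int = 7,
    n_background_sets: int = 20,
) -> tuple[dict[str, ComparisonResult], pd.DataFrame]:
    """Pooled signature-vs-background comparison on all three metrics.

    Mean expression and entropy are computed per gene across cells for the
    pooled signature genes and every background gene.  Inter-gene
    correlation compares the signature set against ``n_background_sets``
    seeded random background gene sets of equal size.
    """
    E = _expr_frame(expr)
    sig_genes = [g for g in signatures.all_genes() if g in E.columns]
    if not sig_genes:
        raise ValueError("no signature genes present in expression matrix")
    bg_genes = [g for g in E.columns if g not in set(sig_genes)]
    rng = np.random.default_rng(seed)

    rows = []
    results: dict[str, ComparisonResult] = {}

    mean_sig = E[sig_genes].mean().to_numpy()
    mean_bg = E[bg_genes].mean().to_numpy()
    results["mean_expression"] = compare_to_background(mean_sig, mean_bg, "mean_expression")
    ent_sig = np.array([gene_entropy(E[g], n_bins) for g in sig_genes])
    ent_bg = np.array([gene_entropy(E[g], n_bins) for g in bg_genes])
    results["entropy_bits"] = compare_to_background(ent_sig, ent_bg, "entropy_bits")

    corr_sig = intergene_correlation(E, sig_genes, method=method).dropna().to_numpy()
    corr_bg_vals = []
    for _ in range(n_background_sets):
        sample = rng.choice(bg_genes, size=len(sig_genes), replace=False)
        corr_bg_vals.append(
            intergene_correlation(E, list(sample), method=method).dropna().to_numpy()
        )
    corr_bg = np.concatenate(corr_bg_vals)
    results["intergene_corr"] = compare_to_background(corr_sig, corr_bg, "intergene_corr")

    for name, (sv, bv) in {
        "mean_expression": (mean_sig, mean_bg),
        "entropy_bits": (ent_sig, ent_bg),
        "intergene_corr": (corr_sig, corr_bg),
    }.items():
        rows.append(
            pd.DataFrame(
                {
                    "metric": name,
                    "group": ["signature"] * len(sv) + ["background"] * len(bv),
                    "value": np.concatenate([sv, bv]),
                }
            )
        )
    return results, pd.concat(rows, ignore_index=True)
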