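"""Signature expression versus drug response in subtype-labeled cell lines.

Two complementary views, both on ln(IC50): a median split of the lines by
signature score with a two-sided Mann-Whitney test per drug, and the
Spearman correlation between score and ln(IC50).  A negative
shift/correlation means higher signature expression goes with a lower
IC50, i.e. increased sensitivity; positive means resistance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cm1_signatures import SignatureSet
from .survival_eval import signature_score


def median_split(values: pd.Series) -> pd.Series:
    """Label each line "high" (strictly above the median) or "low" (at or below)."""
    v = pd.Series(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need >= 2 lines")
    if v.nunique() == 1:
        raise ValueError("all values identical; median split undefined")
    med = v.median()
    return pd.Series(np.where(v > med, "high", "low"), index=v.index, name="group")


@dataclass
class DrugComparison:
    drug: str
    statistic: float
    p_value: float
    direction: int  # sign(median high - median low); -1 = more sensitive
    n_high: int
    n_low: int


def compare_ic50(
    groups: pd.Series,
    ic50: pd.DataFrame,
    drug: str,
    exact_max_n: int = 12,
) -> DrugComparison:
    """Two-sided Mann-Whitney comparison of a drug's ln(IC50) between groups.

    Missing IC50 values are dropped per drug; exact enumeration is used
    for total n <= ``exact_max_n`` (and by scipy's own policy for other
    small tie-free samples), the tie-corrected normal approximation
    otherwise.
    """
    y = ic50[drug].reindex(groups.index)
    ok = y.notna()
    hi = y[ok & (groups == "high")].to_numpy(dtype=float)
    lo = y[ok & (groups == "low")].to_numpy(dtype=float)
    if min(hi.size, lo.size) < 2:
        raise ValueError(
            f"drug {drug!r} skipped: fewer than 2 non-missing lines per group "
            f"(high={hi.size}, low={lo.size})"
        )
    if np.unique(np.concatenate([hi, lo])).size == 1:
        return DrugComparison(drug, hi.size * lo.size / 2.0, 1.0, 0, hi.size, lo.size)
    method = "exact" if hi.size + lo.size <= exact_max_n else "auto"
    try:
        res = stats.mannwhitneyu(hi, lo, alternative="two-sided", method=method)
    except ValueError:  # exact method rejects ties
        res = stats.mannwhitneyu(hi, lo, alternative="two-sided", method="asymptotic")
    direction = int(np.sign(np.median(hi) - np.median(lo)))
    return DrugComparison(
        drug, float(res.statistic), float(min(res.pvalue, 1.0)), direction,
        hi.size, lo.size,
    )


def spearman_drug_corr(sig_expr, ic50_values) -> tuple[float, float]:
    """Spearman rho (average ranks for ties) and two-sided p between score and ln(IC50)."""
    x = np.asarray(sig_expr, dtype=float)
    y = np.asarray(ic50_values, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 4:
        raise ValueError("need >= 4 paired non-missing values")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("constant input vector; correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def drug_response_screen(
    expr: pd.DataFrame,
    ic50: pd.DataFrame,
    signatures: SignatureSet,
    labels: pd.Series,
    subtypes: Optional[Sequence[str]] = None,
    min_lines: int = 3,
    score_mode: str = "signed_mean",
) -> pd.DataFrame:
    """Per-subtype, per-drug median-split test and Spearman correlation.

    For each subtype the lines carrying that label are scored with the
    subtype's signature; drugs with fewer than ``min_lines`` non-missing
    lines, or with too few lines per split group, are recorded as skipped
    with the reason.
    """
    if subtypes is None:
        subtypes = signatures.subtypes
    rows = []
    for s in subtypes:
        lines = labels.index[labels == s]
        lines = lines.intersection(expr.index).intersection(ic50.index)
        if len(lines) < 2:
            warnings.warn(f"subtype {s}: fewer than 2 labeled lines; skipped", RuntimeWarning)
            continue
        score = signature_score(expr.loc[lines], (signatures, s), mode=score_mode)
        groups = median_split(score)
        for drug in ic50.columns:
            y = ic50.loc[lines, drug]
            base = {"subtype": s, "drug": drug, "n_lines": int(y.notna().sum())}
            if y.notna().sum() < min_lines:
                rows.append({**base, "skipped": "fewer than min_lines non-missing"})
                continue
            try:
                cmp_res = compare_ic50(groups, ic50.loc[lines], drug)
                split = {
                    "split_statistic": cmp_res.statistic,
                    "split_p": cmp_res.p_value,
                    "direction": cmp_res.direction,
                }
            except ValueError as err:
                split = {"skipped": str(err)}
            try:
                rho, p = spearman_drug_corr(score.loc[y.index], y)
                corr = {"spearman_rho": rho, "spearman_p": p}
            except ValueError as err:
                corr = {"skipped": str(err)}
            rows.append({**base, **split, **corr})
    return pd.DataFrame(rows)
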