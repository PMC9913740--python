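"""CM1-score marker selection and subtype-specific signature assembly.

The CM1 score of gene *i* for a subtype is

    CM1_i = (x̄_i − ȳ_i) / (1 + (max{y_i} − min{y_i}))

where x̄_i is the gene's mean expression inside the subtype, ȳ_i its mean
outside, and max{y_i}/min{y_i} the extreme expression values observed
outside the subtype.  Large positive scores mark genes specifically
up-regulated in the subtype (stable and low elsewhere); large negative
scores mark specific down-regulation.  Per subtype, the top and bottom k
genes of the descending CM1 ranking become candidate markers, and genes
shared between any two subtypes' candidate lists are removed everywhere
to leave pairwise-disjoint signatures.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Union

import numpy as np
import pandas as pd
import anndata as ad

from .subtype_classifier import UNASSIGNED, _expr_frame


def _label_series(labels) -> pd.Series:
    if isinstance(labels, pd.DataFrame):
        return labels["label"]
    return pd.Series(labels)


def cm1_scores(
    expr: Union[ad.AnnData, pd.DataFrame],
    labels,
    subtype: str,
    range_over: str = "cells",
) -> pd.DataFrame:
    """One CM1 row per gene for ``subtype`` versus all other assigned cells.

    ``labels`` is a per-cell subtype label (Series, or the classifier's
    output DataFrame); unassigned cells are excluded from both groups.
    ``range_over`` selects whether the denominator range max{y}-min{y} is
    taken over individual out-of-subtype cells ("cells", default) or over
    the per-subtype means ("subtype_means").
    """
    if range_over not in ("cells", "subtype_means"):
        raise ValueError("range_over must be 'cells' or 'subtype_means'")
    E = _expr_frame(expr)
    lab = _label_series(labels).reindex(E.index)
    if lab.isna().any():
        raise ValueError("labels do not cover all cells of the expression matrix")
    assigned = lab != UNASSIGNED
    in_mask = (lab == subtype) & assigned
    out_mask = assigned & ~in_mask
    if subtype not in set(lab[assigned]):
        raise ValueError(f"subtype {subtype!r} absent from labels")
    if in_mask.sum() < 2 or out_mask.sum() < 2:
        raise ValueError("need >= 2 cells inside and outside the subtype")

    X = E.to_numpy(dtype=float)
    x_bar = X[in_mask.to_numpy()].mean(axis=0)
    Y = X[out_mask.to_numpy()]
    y_bar = Y.mean(axis=0)
    if range_over == "cells":
        y_max = Y.max(axis=0)
        y_min = Y.min(axis=0)
    else:
        means = np.stack(
            [
                X[(lab == s).to_numpy()].mean(axis=0)
                for s in sorted(set(lab[out_mask.to_numpy()]))
            ]
        )
        y_max = means.max(axis=0)
        y_min = means.min(axis=0)
    cm1 = (x_bar - y_bar) / (1.0 + (y_max - y_min))
    return pd.DataFrame(
        {
            "gene_id": E.columns,
            "subtype": subtype,
            "cm1": cm1,
            "x_bar": x_bar,
            "y_bar": y_bar,
            "y_max": y_max,
            "y_min": y_min,
        }
    ).set_index("gene_id")


def select_candidates(table: pd.DataFrame, k: int = 4) -> pd.DataFrame:
    """Top-k (up) and bottom-k (down) genes of the descending CM1 ranking.

    Ties are broken by lexicographic gene id.  An "up" candidate must have
    cm1 > 0 and a "down" candidate cm1 < 0; violating genes are dropped
    with a warning, so fewer than 2k genes may be returned.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(table) < 2 * k:
        raise ValueError(f"need >= {2 * k} genes, got {len(table)}")
    t = table.reset_index()
    desc = t.sort_values(["cm1", "gene_id"], ascending=[False, True])
    asc = t.sort_values(["cm1", "gene_id"], ascending=[True, True])
    up = desc.head(k).assign(direction="up")
    down = asc.head(k).assign(direction="down").iloc[::-1]

    bad_up = up["cm1"] <= 0
    bad_down = down["cm1"] >= 0
    if bad_up.any() or bad_down.any():
        warnings.warn(
            f"dropped {int(bad_up.sum())} up / {int(bad_down.sum())} down "
            "candidate(s) with CM1 sign inconsistent with direction",
            RuntimeWarning,
        )
    sel = pd.concat([up[~bad_up], down[~bad_down]])
    return sel[["gene_id", "direction", "cm1"]].reset_index(drop=True)


@dataclass
class SignatureSet:
    """Per-subtype marker lists with direction flags, pairwise disjoint."""

    signatures: dict[str, pd.DataFrame] = field(default_factory=dict)

    def genes(self, subtype: str) -> list[str]:
        return self.signatures[subtype]["gene_id"].tolist()

    def all_genes(self) -> list[str]:
        out: list[str] = []
        for df in self.signatures.values():
            out.extend(df["gene_id"].tolist())
        return out

    def directions(self, subtype: str) -> pd.Series:
        df = self.signatures[subtype]
        return pd.Series(df["direction"].to_numpy(), index=df["gene_id"])

    @property
    def subtypes(self) -> list[str]:
        return list(self.signatures)

    def to_json(self, path: Union[str, Path, None] = None) -> str:
        obj = {
            s: df[["gene_id", "direction", "cm1"]].rename(
                columns={"gene_id": "gene"}
            ).to_dict("records")
            for s, df in self.signatures.items()
        }
        text = json.dumps(obj, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, src: Union[str, Path]) -> "SignatureSet":
        p = Path(src)
        obj = json.loads(p.read_text() if p.exists() else str(src))
        sigs = {
            s: pd.DataFrame(rows, columns=["gene", "direction", "cm1"]).rename(
                columns={"gene": "gene_id"}
            )
            for s, rows in obj.items()
        }
        return cls(sigs)


def remove_overlaps(candidates: Mapping[str, pd.DataFrame]) -> SignatureSet:
    """Remove every gene occurring in two or more candidate lists from all of them."""
    if len(candidates) < 2:
        raise ValueError("need candidate lists for >= 2 subtypes")
    counts: dict[str, int] = {}
    for df in candidates.values():
        for g in set(df["gene_id"]):
            counts[g] = counts.get(g, 0) + 1
    shared = {g for g, c in counts.items() if c > 1}
    out: dict[str, pd.DataFrame] = {}
    for s, df in candidates.items():
        kept = df[~df["gene_id"].isin(shared)].reset_index(drop=True)
        if kept.empty:
            warnings.warn(f"signature for {s} is empty after overlap removal", RuntimeWarning)
        out[s] = kept
    return SignatureSet(out)


def discover_signatures(
    expr,
    labels,
    subtypes=None,
    k: int = 4,
    range_over: str = "cells",
) -> tuple[SignatureSet, pd.DataFrame]:
    """CM1 scoring + candidate selection + overlap removal for every subtype.

    Returns the disjoint :class:`SignatureSet` and the concatenated CM1
    table across subtypes.
    """
    lab = _label_series(labels)
    if subtypes is None:
        subtypes = [s for s in pd.unique(lab) if s != UNASSIGNED]
    tables = {s: cm1_scores(expr, labels, s, range_over=range_over) for s in subtypes}
    cands = {s: select_candidates(t, k=k) for s, t in tables.items()}
    sigs = remove_overlaps(cands)
    full = pd.concat([t.reset_index() for t in tables.values()], ignore_index=True)
    return sigs, full
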