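"""Prognostic validation of signatures on bulk cohorts.

Pipeline: a per-sample risk score from the signature genes (signed
z-score mean by default), dichotomization at the maximally selected
rank-statistic cutpoint, Kaplan-Meier curves with a log-rank test, and
uni-/multivariate Cox proportional-hazards models with a points-based
nomogram, calibration curve and time-dependent (cumulative/dynamic,
IPCW-weighted) ROC AUC.

The reported p-value for the dichotomized groups is the naive log-rank p
of the optimized split, matching common practice; because the cutpoint is
chosen to maximize that very statistic this p is anti-conservative under
the null — callers comparing risk groups should treat it as descriptive.
Cox models use Efron tie handling via lifelines; the log-rank machinery
used for the cutpoint scan is implemented here directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import chi2
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from sksurv.metrics import cumulative_dynamic_auc
from sksurv.util import Surv

from .cm1_signatures import SignatureSet

DEFAULT_COVARIATES = ("age", "tumor_size", "stage_iii", "chemotherapy", "hormone_therapy")


# ---------------------------------------------------------------- risk score

def signature_score(
    expr: pd.DataFrame,
    signature: Union[pd.DataFrame, tuple[SignatureSet, str]],
    mode: str = "signed_mean",
) -> pd.Series:
    """Per-sample risk score from a signature's genes.

    ``signature`` is either a DataFrame with columns ``gene_id`` and
    ``direction`` or a ``(SignatureSet, subtype)`` pair.  Modes:

    - ``signed_mean`` (default): mean of per-gene z-scores, down-regulated
      genes entering with negative sign;
    - ``mean``: unsigned mean of z-scores;
    - ``pc1``: first principal component of the z-scored submatrix, signed
      to correlate positively with the signed mean.
    """
    if isinstance(signature, tuple):
        sigset, subtype = signature
        sig = sigset.signatures[subtype]
    else:
        sig = signature
    genes = sig["gene_id"].tolist()
    present = [g for g in genes if g in expr.columns]
    if not present:
        raise ValueError("no signature genes present in cohort expression")
    if len(present) < len(genes):
        warnings.warn(
            f"{len(genes) - len(present)} signature gene(s) missing from cohort; dropped",
            RuntimeWarning,
        )
    X = expr[present].to_numpy(dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    Z = np.where(sd > 0, (X - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    direction = sig.set_index("gene_id")["direction"].reindex(present)
    signs = np.where(direction.to_numpy() == "down", -1.0, 1.0)

    if mode == "signed_mean":
        score = (Z * signs).mean(axis=1)
    elif mode == "mean":
        score = Z.mean(axis=1)
    elif mode == "pc1":
        U, S, Vt = np.linalg.svd(Z - Z.mean(axis=0), full_matrices=False)
        score = U[:, 0] * S[0]
        ref = (Z * signs).mean(axis=1)
        if np.dot(score, ref) < 0:
            score = -score
    else:
        raise ValueError(f"unknown score mode {mode!r}")
    return pd.Series(score, index=expr.index, name="risk_score")


# ------------------------------------------------------- log-rank machinery

def _logrank_oev(time: np.ndarray, event: np.ndarray, mask: np.ndarray):
    """Observed, expected and hypergeometric variance of group-1 events."""
    ut, inv = np.unique(time, return_inverse=True)
    k = ut.size
    n_at_time = np.bincount(inv, minlength=k)
    g_at_time = np.bincount(inv, weights=mask.astype(float), minlength=k)
    d_tot = np.bincount(inv, weights=event.astype(float), minlength=k)
    d_grp = np.bincount(inv, weights=(event * mask).astype(float), minlength=k)
    # at-risk counts: subjects with time >= ut  (reverse cumulative sums)
    Y = n_at_time[::-1].cumsum()[::-1].astype(float)
    Yg = g_at_time[::-1].cumsum()[::-1]
    keep = d_tot > 0
    O = d_grp[keep].sum()
    E = (d_tot[keep] * Yg[keep] / Y[keep]).sum()
    Yk, Ygk, dk = Y[keep], Yg[keep], d_tot[keep]
    with np.errstate(invalid="ignore", divide="ignore"):
        v = dk * (Ygk / Yk) * (1 - Ygk / Yk) * (Yk - dk) / (Yk - 1)
    V = v[Yk > 1].sum()
    return O, E, V


def logrank_test(time, event, group) -> tuple[float, float]:
    """Two-group log-rank test: chi-square(1) statistic and two-sided p."""
    t = np.asarray(time, dtype=float)
    d = np.asarray(event, dtype=float)
    g = np.asarray(group)
    levels = np.unique(g)
    if levels.size != 2:
        raise ValueError(f"log-rank test needs exactly 2 groups, got {levels.size}")
    if d.sum() < 1:
        raise ValueError("no events")
    O, E, V = _logrank_oev(t, d, g == levels[1])
    if V <= 0:
        return 0.0, 1.0
    stat = (O - E) ** 2 / V
    return float(stat), float(chi2.sf(stat, 1))


def km_estimate(time, event, group=None) -> dict:
    """Product-limit survival curves, one per group (single group if None).

    Returns ``{group: pd.Series}`` with index the timeline (including 0,
    where S=1) and values the survival probability.
    """
    t = np.asarray(time, dtype=float)
    d = np.asarray(event, dtype=float)
    g = np.zeros(len(t)) if group is None else np.asarray(group)
    out = {}
    for lev in np.unique(g):
        m = g == lev
        kmf = KaplanMeierFitter()
        kmf.fit(t[m], d[m])
        s = kmf.survival_function_["KM_estimate"]
        s.index.name = "time"
        out[lev] = s
    return out


# ------------------------------------------------------------ cutpoint scan

@dataclass
class CutpointResult:
    """Maximally selected rank-statistic split of a risk score."""

    threshold: float
    max_standardized_statistic: float
    n_high: int
    n_low: int
    p_naive: float  # log-rank p of the selected split; anti-conservative


def optimal_cutpoint(
    scores, time, event, minprop: float = 0.1
) -> CutpointResult:
    """Threshold maximizing the standardized two-group log-rank statistic.

    Every unique score value whose split (high = score > threshold)
    leaves at least ``minprop`` of the samples in each group is evaluated;
    the threshold with the largest |standardized statistic| wins (ties ->
    smallest threshold).
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(time, dtype=float)
    d = np.asarray(event, dtype=float)
    n = s.size
    if n < 10:
        raise ValueError("need n >= 10")
    if d.sum() < 1:
        raise ValueError("no events")
    if not 0 < minprop < 0.5:
        raise ValueError("minprop must be in (0, 0.5)")
    uniq = np.unique(s)
    if uniq.size < 2:
        raise ValueError("all scores identical")

    best = None
    for thr in uniq[:-1]:
        high = s > thr
        nh = int(high.sum())
        if min(nh, n - nh) < minprop * n:
            continue
        O, E, V = _logrank_oev(t, d, high)
        if V <= 0:
            continue
        z = abs(O - E) / np.sqrt(V)
        if best is None or z > best[0] + 1e-12:
            best = (z, thr, nh)
    if best is None:
        raise ValueError("no threshold satisfies the minprop constraint")
    z, thr, nh = best
    p = float(chi2.sf(z ** 2, 1))
    return CutpointResult(float(thr), float(z), nh, n - nh, p)


# --------------------------------------------------------------- Cox models

@dataclass
class HazardModel:
    """Fitted proportional-hazards model (Efron ties, Breslow baseline)."""

    coefficients: pd.Series
    covariance: pd.DataFrame
    hazard_ratios: pd.Series
    conf_int: pd.DataFrame  # columns: hr_lower, hr_upper (95%)
    p_values: pd.Series
    baseline_cumulative_hazard: pd.Series
    baseline_survival: pd.Series
    covariate_means: pd.Series
    fitter: CoxPHFitter

    def linear_predictor(self, X: pd.DataFrame) -> pd.Series:
        lp = X[self.coefficients.index].to_numpy() @ self.coefficients.to_numpy()
        return pd.Series(lp, index=X.index, name="lp")

    def baseline_survival_at(self, t: float) -> float:
        """Step interpolation of the baseline survival (at mean covariates)."""
        s = self.baseline_survival
        idx = s.index.to_numpy()
        if t < idx.min():
            return 1.0
        if t > idx.max():
            warnings.warn(
                f"horizon {t} beyond last observed time; extrapolated flat",
                RuntimeWarning,
            )
            return float(s.iloc[-1])
        return float(s[idx[idx <= t].max()])

    def predict_survival(self, X: pd.DataFrame, t: float) -> pd.Series:
        """S(t | x) = S0(t)^exp(lp(x) - lp(mean))."""
        s0 = self.baseline_survival_at(t)
        lp = self.linear_predictor(X)
        lp_mean = float(
            self.covariate_means[self.coefficients.index].to_numpy()
            @ self.coefficients.to_numpy()
        )
        return np.power(s0, np.exp(lp - lp_mean))


def fit_hazard_model(
    cohort: pd.DataFrame,
    covariates: Sequence[str],
    duration_col: str = "time",
    event_col: str = "event",
) -> HazardModel:
    """Cox proportional-hazards fit of ``covariates`` on the cohort."""
    covariates = list(covariates)
    df = cohort[[duration_col, event_col] + covariates].dropna()
    if len(df) <= len(covariates):
        raise ValueError("need more samples than covariates")
    if df[event_col].sum() < 1:
        raise ValueError("no events")
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col=duration_col, event_col=event_col)
    except ConvergenceError as err:
        raise RuntimeError(
            f"proportional-hazards fit failed to converge for {covariates}: {err}"
        ) from err
    summary = cph.summary
    return HazardModel(
        coefficients=cph.params_.copy(),
        covariance=cph.variance_matrix_.copy(),
        hazard_ratios=summary["exp(coef)"].copy(),
        conf_int=summary[["exp(coef) lower 95%", "exp(coef) upper 95%"]].rename(
            columns={"exp(coef) lower 95%": "hr_lower", "exp(coef) upper 95%": "hr_upper"}
        ),
        p_values=summary["p"].copy(),
        baseline_cumulative_hazard=cph.baseline_cumulative_hazard_.iloc[:, 0],
        baseline_survival=cph.baseline_survival_.iloc[:, 0],
        covariate_means=df[covariates].mean(),
        fitter=cph,
    )


def cox_table(
    cohort: pd.DataFrame,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    duration_col: str = "time",
    event_col: str = "event",
) -> pd.DataFrame:
    """Univariate + multivariate HR / 95% CI / p table for every covariate."""
    rows = []
    multi = fit_hazard_model(cohort, covariates, duration_col, event_col)
    for cov in covariates:
        uni = fit_hazard_model(cohort, [cov], duration_col, event_col)
        rows.append(
            {
                "variable": cov,
                "uni_hr": uni.hazard_ratios[cov],
                "uni_ci_low": uni.conf_int.loc[cov, "hr_lower"],
                "uni_ci_high": uni.conf_int.loc[cov, "hr_upper"],
                "uni_p": uni.p_values[cov],
                "multi_hr": multi.hazard_ratios[cov],
                "multi_ci_low": multi.conf_int.loc[cov, "hr_lower"],
                "multi_ci_high": multi.conf_int.loc[cov, "hr_upper"],
                "multi_p": multi.p_values[cov],
            }
        )
    return pd.DataFrame(rows).set_index("variable")


# ----------------------------------------------------------------- nomogram

@dataclass
class NomogramTable:
    """Points-based rendering of a hazard model.

    Each covariate's contribution to the linear predictor over its range
    is mapped to a 0-100 point scale; the covariate with the largest
    |coefficient| x range spans exactly 0-100.  Total points map back to
    predicted survival through the baseline survival function.
    """

    coefficients: pd.Series
    references: pd.Series  # covariate value worth 0 points (lowest risk end)
    scale: float  # linear-predictor span worth 100 points
    model: HazardModel
    horizons: tuple[float, ...]

    def points(self, covariate: str, value: float) -> float:
        c = self.coefficients[covariate]
        return 100.0 * c * (value - self.references[covariate]) / self.scale

    def total_points(self, X: pd.DataFrame) -> pd.Series:
        tot = np.zeros(len(X))
        for cov in self.coefficients.index:
            tot += np.asarray([self.points(cov, v) for v in X[cov]])
        return pd.Series(tot, index=X.index, name="total_points")

    def survival_at(self, total_points: float, horizon: float) -> float:
        """Predicted S(horizon) for a given total-point count."""
        lp_ref = float(
            self.references[self.coefficients.index].to_numpy()
            @ self.coefficients.to_numpy()
        )
        lp = lp_ref + self.scale * total_points / 100.0
        lp_mean = float(
            self.model.covariate_means[self.coefficients.index].to_numpy()
            @ self.coefficients.to_numpy()
        )
        s0 = self.model.baseline_survival_at(horizon)
        return float(s0 ** np.exp(lp - lp_mean))

    def to_table(self, max_total: Optional[float] = None, step: float = 20.0) -> pd.DataFrame:
        if max_total is None:
            max_total = 100.0 * len(self.coefficients)
        grid = np.arange(0.0, max_total + step / 2, step)
        rows = {"total_points": grid}
        for h in self.horizons:
            rows[f"surv_{h:g}"] = [self.survival_at(tp, h) for tp in grid]
        return pd.DataFrame(rows)


def build_nomogram(
    model: HazardModel,
    covariate_ranges: dict[str, tuple[float, float]],
    horizons: Sequence[float],
) -> NomogramTable:
    """Points table from a fitted model and the clinical range of each covariate."""
    coefs = model.coefficients
    missing = [c for c in coefs.index if c not in covariate_ranges]
    if missing:
        raise KeyError(f"ranges missing for covariates: {missing}")
    refs = {}
    spans = {}
    for cov in coefs.index:
        lo, hi = covariate_ranges[cov]
        if hi < lo:
            raise ValueError(f"invalid range for {cov}")
        refs[cov] = lo if coefs[cov] >= 0 else hi
        spans[cov] = abs(coefs[cov]) * (hi - lo)
    scale = max(spans.values())
    if scale <= 0:
        raise ValueError("all covariates have zero coefficient x range")
    last_t = model.baseline_survival.index.max()
    for h in horizons:
        if h > last_t:
            warnings.warn(
                f"horizon {h} beyond observed time range ({last_t}); flat extrapolation",
                RuntimeWarning,
            )
    return NomogramTable(
        coefficients=coefs.copy(),
        references=pd.Series(refs),
        scale=float(scale),
        model=model,
        horizons=tuple(float(h) for h in horizons),
    )


# -------------------------------------------------------------- calibration

def calibration_curve(
    model: HazardModel,
    cohort: pd.DataFrame,
    horizon: float,
    n_bins: int = 3,
    duration_col: str = "time",
    event_col: str = "event",
    min_bin_size: int = 10,
) -> pd.DataFrame:
    """Mean predicted vs KM-observed survival at ``horizon`` per risk bin.

    Samples are binned by predicted survival (quantile bins); adjacent
    bins smaller than ``min_bin_size`` are merged.  Observed survival is
    the product-limit estimate within the bin with its 95% CI.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    pred = model.predict_survival(cohort, horizon)
    order = np.argsort(pred.to_numpy(), kind="stable")
    n = len(pred)
    n_bins = max(1, min(n_bins, n // max(min_bin_size, 1)) or 1)
    edges = [round(i * n / n_bins) for i in range(n_bins + 1)]
    bins = [order[edges[i]:edges[i + 1]] for i in range(n_bins) if edges[i] < edges[i + 1]]
    # merge undersized bins into their left neighbour
    merged: list[np.ndarray] = []
    for b in bins:
        if merged and len(b) < min_bin_size:
            merged[-1] = np.concatenate([merged[-1], b])
        else:
            merged.append(b)
    if len(merged) > 1 and len(merged[0]) < min_bin_size:
        merged[1] = np.concatenate([merged[0], merged[1]])
        merged = merged[1:]

    rows = []
    for b in merged:
        sub = cohort.iloc[b]
        kmf = KaplanMeierFitter()
        kmf.fit(sub[duration_col], sub[event_col])
        obs = float(kmf.survival_function_at_times(horizon).iloc[0])
        ci = kmf.confidence_interval_survival_function_
        tidx = ci.index.to_numpy()
        at = tidx[tidx <= horizon]
        if at.size:
            lo, hi = ci.loc[at.max()].to_numpy()
        else:
            lo, hi = 1.0, 1.0
        rows.append(
            {
                "n": len(b),
                "mean_predicted": float(pred.iloc[b].mean()),
                "km_observed": obs,
                "km_ci_low": float(lo),
                "km_ci_high": float(hi),
            }
        )
    return pd.DataFrame(rows)


# ------------------------------------------------------- time-dependent AUC

def time_dependent_auc(scores, time, event, horizon: float) -> float:
    """Cumulative/dynamic AUC at ``horizon`` with IPCW censoring weights."""
    s = np.asarray(scores, dtype=float)
    t = np.asarray(time, dtype=float)
    d = np.asarray(event, dtype=bool)
    if not ((t <= horizon) & d).any():
        raise ValueError("no events at or before the horizon")
    if not (t > horizon).any():
        raise ValueError("no subjects at risk beyond the horizon")
    y = Surv.from_arrays(event=d, time=t)
    auc, _ = cumulative_dynamic_auc(y, y, s, [horizon])
    return float(auc[0])


# --------------------------------------------------------------- pipelines

@dataclass
class RiskStratification:
    """Score -> cutpoint -> risk groups -> KM/log-rank summary."""

    scores: pd.Series
    cutpoint: CutpointResult
    groups: pd.Series  # "high"/"low"
    logrank_statistic: float
    logrank_p: float
    hazard_ratio: float  # high vs low, univariate Cox on the group indicator
    km: dict


def risk_stratify(
    expr: pd.DataFrame,
    clinical: pd.DataFrame,
    signature,
    score_mode: str = "signed_mean",
    minprop: float = 0.1,
    duration_col: str = "time",
    event_col: str = "event",
) -> RiskStratification:
    """The full per-subtype prognosis evaluation on one cohort."""
    common = expr.index.intersection(clinical.index)
    if common.empty:
        raise ValueError("no samples shared between expression and clinical tables")
    expr = expr.loc[common]
    clinical = clinical.loc[common]
    scores = signature_score(expr, signature, mode=score_mode)
    cut = optimal_cutpoint(
        scores.to_numpy(), clinical[duration_col], clinical[event_col], minprop
    )
    groups = pd.Series(
        np.where(scores > cut.threshold, "high", "low"), index=common, name="risk_group"
    )
    stat, p = logrank_test(clinical[duration_col], clinical[event_col], groups)
    df = pd.DataFrame(
        {
            duration_col: clinical[duration_col],
            event_col: clinical[event_col],
            "high": (groups == "high").astype(float),
        }
    )
    try:
        hr = float(
            fit_hazard_model(df, ["high"], duration_col, event_col).hazard_ratios["high"]
        )
    except RuntimeError as err:
        # an optimized split can perfectly separate events (monotone
        # likelihood); the group HR is then unbounded and reported as NaN
        warnings.warn(f"risk-group hazard ratio undefined: {err}", RuntimeWarning)
        hr = float("nan")
    km = km_estimate(clinical[duration_col], clinical[event_col], groups)
    return RiskStratification(scores, cut, groups, stat, p, hr, km)
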