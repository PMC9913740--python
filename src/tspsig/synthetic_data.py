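"""Synthetic inputs with the statistical structure the pipeline assumes.

Three generators cover the three data modalities: negative-binomial UMI
counts with cell size factors and planted subtype markers, right-censored
survival cohorts whose hazard follows a proportional-hazards model in the
signature score and clinical covariates, and cell-line panels whose
ln(IC50) values carry planted Spearman correlations with signature
expression through a Gaussian copula.  Every generator is a pure function
of (configuration, seed) and records its ground truth for closed-loop
testing.

The count generator emulates a droplet scRNA-seq experiment on a single
annotated tumor-cell population split across the four TNBC subtypes:
gene baseline means are log-normal (heavily skewed, as UMI data are),
library sizes vary through log-normal cell size factors, and marker
genes are shifted by +/- log_fc (log2 units) in their subtype only.
Marker genes are drawn from the upper half of the baseline-expression
distribution: a subtype marker that is not detectable is of no use to a
nearest-centroid panel, and published subtype panels are built from
well-detected genes.  Centroids are the true per-subtype mean
log-expression over the marker panel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import anndata as ad
from scipy.stats import norm

from .cm1_signatures import SignatureSet

SUBTYPES = ("BL1", "BL2", "LAR", "M")


@dataclass
class SimulationTruth:
    """Ground truth of a synthetic data set; regenerable bit-identically from (config, seed)."""

    seed: int
    config: dict = field(default_factory=dict)
    markers: Optional[dict] = None  # subtype -> {"up": [...], "down": [...]}
    size_factors: Optional[pd.Series] = None
    labels: Optional[pd.Series] = None
    hazard_coefficients: Optional[dict] = None
    cutpoint: Optional[float] = None
    drug_rho: Optional[dict] = None

    def to_json(self, path: Union[str, Path, None] = None) -> str:
        obj = {"seed": self.seed, "config": self.config}
        if self.markers is not None:
            obj["markers"] = self.markers
        if self.size_factors is not None:
            obj["size_factors"] = self.size_factors.round(10).to_dict()
        if self.labels is not None:
            obj["labels"] = self.labels.to_dict()
        if self.hazard_coefficients is not None:
            obj["hazard_coefficients"] = self.hazard_coefficients
        if self.cutpoint is not None:
            obj["cutpoint"] = self.cutpoint
        if self.drug_rho is not None:
            obj["drug_rho"] = self.drug_rho
        text = json.dumps(obj, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


# ------------------------------------------------------------- UMI counts

def simulate_counts(
    n_cells_per_subtype: Union[int, dict] = 300,
    n_genes: int = 2000,
    n_markers_up: int = 4,
    n_markers_down: int = 4,
    log_fc: float = 2.0,
    dispersion: float = 0.5,
    size_factor_sd: float = 0.25,
    baseline_meanlog: float = np.log(0.3),
    baseline_sdlog: float = 1.2,
    marker_min_mean: float = 1.0,
    seed: int = 0,
) -> tuple[ad.AnnData, pd.DataFrame, SimulationTruth]:
    """NB UMI counts for four subtypes with planted up/down markers.

    counts[c,g] ~ NB(mean = sf_c * base_g * 2^(delta_gs), dispersion) with
    delta = +log_fc on the subtype's up markers, -log_fc on its down
    markers, 0 elsewhere (log_fc = 0 plants nothing).  Returns the count
    AnnData (true labels in ``obs``), the marker-panel centroid matrix and
    the recorded truth.
    """
    if log_fc < 0:
        raise ValueError("log_fc must be >= 0")
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    if isinstance(n_cells_per_subtype, int):
        n_per = {s: n_cells_per_subtype for s in SUBTYPES}
    else:
        n_per = dict(n_cells_per_subtype)
    n_marker_total = len(n_per) * (n_markers_up + n_markers_down)
    if n_marker_total > n_genes:
        raise ValueError("marker demand exceeds n_genes")

    rng = np.random.default_rng(seed)
    genes = np.array([f"G{i:05d}" for i in range(n_genes)])
    base = rng.lognormal(baseline_meanlog, baseline_sdlog, n_genes)

    # Markers must be detectable: a gene down-regulated from a baseline of
    # ~0.3 UMI/cell is zero nearly everywhere and cannot be observed as
    # "down".  Real signature genes are well-detected, so marker genes are
    # drawn from genes with baseline mean >= marker_min_mean counts/cell.
    eligible = np.flatnonzero(base >= marker_min_mean)
    if eligible.size < n_marker_total:
        eligible = np.argsort(base)[-n_marker_total:]
    picked = rng.choice(eligible, size=n_marker_total, replace=False)
    markers: dict[str, dict[str, list[str]]] = {}
    delta = {}  # gene index -> (subtype, shift)
    pos = 0
    for s in n_per:
        up = picked[pos : pos + n_markers_up]
        pos += n_markers_up
        down = picked[pos : pos + n_markers_down]
        pos += n_markers_down
        markers[s] = {"up": genes[up].tolist(), "down": genes[down].tolist()}
        for g in up:
            delta[g] = (s, log_fc)
        for g in down:
            delta[g] = (s, -log_fc)

    cells, labels = [], []
    for s, n in n_per.items():
        labels += [s] * n
    n_cells = len(labels)
    cells = [f"C{i:05d}" for i in range(n_cells)]
    labels = pd.Series(labels, index=cells, name="true_subtype")
    sf = rng.lognormal(0.0, size_factor_sd, n_cells)

    fold = np.ones((n_cells, n_genes))
    lab_arr = labels.to_numpy()
    for g, (s, d) in delta.items():
        fold[lab_arr == s, g] = 2.0 ** d
    mu = sf[:, None] * base[None, :] * fold
    lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
    counts = rng.poisson(lam)

    adata = ad.AnnData(
        X=counts.astype(np.int64),
        obs=pd.DataFrame(
            {"true_subtype": labels, "cell_label": "Cancer Epithelial"}, index=cells
        ),
        var=pd.DataFrame({"biotype": "protein_coding"}, index=genes),
    )

    panel = sorted(delta)
    cent = {}
    for s in n_per:
        shift = np.array(
            [2.0 ** delta[g][1] if delta[g][0] == s else 1.0 for g in panel]
        )
        cent[s] = np.log2(1.0 + base[panel] * shift)
    centroids = pd.DataFrame(cent, index=genes[panel])
    centroids.index.name = "gene_id"

    truth = SimulationTruth(
        seed=seed,
        config={
            "n_cells_per_subtype": n_per,
            "n_genes": n_genes,
            "n_markers_up": n_markers_up,
            "n_markers_down": n_markers_down,
            "log_fc": log_fc,
            "dispersion": dispersion,
            "size_factor_sd": size_factor_sd,
        },
        markers=markers,
        size_factors=pd.Series(sf, index=cells, name="true_factor"),
        labels=labels,
    )
    return adata, centroids, truth


def simulate_expression_from_centroids(
    centroids: pd.DataFrame,
    n_per_subtype: int = 100,
    noise_sd_ratio: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Units drawn as centroid + Gaussian noise with sd = ratio x centroid SD.

    The noise scale is relative to the spread of each subtype's centroid
    across genes, so ``noise_sd_ratio`` directly controls class overlap.
    """
    rng = np.random.default_rng(seed)
    rows, labels, ids = [], [], []
    for s in centroids.columns:
        col = centroids[s].to_numpy(dtype=float)
        sd = noise_sd_ratio * col.std(ddof=0)
        for i in range(n_per_subtype):
            rows.append(col + rng.normal(0.0, sd, col.size))
            labels.append(s)
            ids.append(f"{s}_{i:04d}")
    expr = pd.DataFrame(rows, index=ids, columns=centroids.index)
    return expr, pd.Series(labels, index=ids, name="true_subtype")


# --------------------------------------------------------------- survival

def _tune_censoring(event_times: np.ndarray, u: np.ndarray, target: float):
    """Bisection on the exponential censoring rate toward the target fraction."""
    def frac(rate):
        return float(np.mean(-np.log(u) / rate < event_times))

    lo, hi = 1e-8, 1e6
    if frac(hi) < target:
        return hi, frac(hi)
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if frac(mid) < target:
            lo = mid
        else:
            hi = mid
    return hi, frac(hi)


def simulate_survival(
    n: int = 300,
    betas: Optional[dict] = None,
    baseline_shape: float = 1.2,
    baseline_scale: float = 72.0,
    censoring: float = 0.3,
    score_effect: str = "linear",
    score_threshold_q: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Right-censored cohort from a Weibull proportional-hazards model.

    Covariates: age ~ N(58, 10), tumor_size ~ N(25, 10) mm (floored at 1),
    stage_iii, chemotherapy, hormone_therapy ~ Bernoulli(0.3, 0.6, 0.3),
    score ~ N(0, 1).  The linear predictor uses centered covariates so
    ``baseline_scale`` (months) is the time scale of a typical patient.
    ``score_effect="threshold"`` replaces the linear score term with a
    step at the ``score_threshold_q`` quantile of N(0,1), planting a true
    change-point for cutpoint-recovery experiments.  Censoring times are
    exponential, their rate tuned by bisection to the target fraction.
    """
    if not 0 <= censoring <= 0.9:
        raise ValueError("censoring target must be in [0, 0.9]")
    if score_effect not in ("linear", "threshold"):
        raise ValueError("score_effect must be 'linear' or 'threshold'")
    betas = dict({"score": 0.7} if betas is None else betas)
    rng = np.random.default_rng(seed)

    df = pd.DataFrame(
        {
            "age": rng.normal(58.0, 10.0, n),
            "tumor_size": np.maximum(rng.normal(25.0, 10.0, n), 1.0),
            "stage_iii": rng.binomial(1, 0.3, n).astype(float),
            "chemotherapy": rng.binomial(1, 0.6, n).astype(float),
            "hormone_therapy": rng.binomial(1, 0.3, n).astype(float),
            "score": rng.normal(0.0, 1.0, n),
        },
        index=[f"S{i:05d}" for i in range(n)],
    )
    centers = {
        "age": 58.0, "tumor_size": 25.0, "stage_iii": 0.3,
        "chemotherapy": 0.6, "hormone_therapy": 0.3, "score": 0.0,
    }
    true_cut = None
    lp = np.zeros(n)
    for cov, b in betas.items():
        if cov == "score" and score_effect == "threshold":
            true_cut = float(norm.ppf(score_threshold_q))
            lp += b * (df["score"].to_numpy() > true_cut)
        else:
            lp += b * (df[cov].to_numpy() - centers[cov])

    u_t = rng.uniform(size=n)
    T = baseline_scale * (-np.log(u_t) / np.exp(lp)) ** (1.0 / baseline_shape)
    if censoring <= 0:
        time, event = T, np.ones(n, dtype=int)
        achieved = 0.0
    else:
        u_c = rng.uniform(size=n)
        rate, achieved = _tune_censoring(T, u_c, censoring)
        if abs(achieved - censoring) > 0.1:
            import warnings

            warnings.warn(
                f"censoring target {censoring} unattainable; achieved {achieved:.2f}",
                RuntimeWarning,
            )
        C = -np.log(u_c) / rate
        event = (T <= C).astype(int)
        time = np.minimum(T, C)
    df["time"] = np.maximum(time, 1e-6)
    df["event"] = event
    df.index.name = "sample_id"

    truth = SimulationTruth(
        seed=seed,
        config={
            "n": n, "baseline_shape": baseline_shape, "baseline_scale": baseline_scale,
            "censoring_target": censoring, "censoring_achieved": achieved,
            "score_effect": score_effect,
        },
        hazard_coefficients=betas,
        cutpoint=true_cut,
    )
    return df, truth


def simulate_bulk_cohort(
    signature: pd.DataFrame,
    n: int = 150,
    beta_score: float = 1.1,
    n_background_genes: int = 100,
    noise_sd: float = 0.5,
    censoring: float = 0.3,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, SimulationTruth]:
    """Bulk expression + clinical table with the hazard tied to a signature score.

    The latent per-sample score drives survival (log-HR ``beta_score``)
    and is spread over the signature genes: up genes are score + noise,
    down genes -score + noise; background genes are pure noise.  Returns
    (expression, clinical, truth).
    """
    clinical, truth = simulate_survival(
        n=n, betas={"score": beta_score}, censoring=censoring, seed=seed
    )
    rng = np.random.default_rng(seed + 1)
    score = clinical["score"].to_numpy()
    cols = {}
    for _, row in signature.iterrows():
        sign = -1.0 if row["direction"] == "down" else 1.0
        cols[row["gene_id"]] = sign * score + rng.normal(0.0, noise_sd, n)
    for i in range(n_background_genes):
        cols[f"BG{i:04d}"] = rng.normal(0.0, 1.0, n)
    expr = pd.DataFrame(cols, index=clinical.index)
    clinical = clinical.drop(columns=["score"])
    return expr, clinical, truth


# -------------------------------------------------------------- cell lines

def default_signature(seed: int = 0) -> SignatureSet:
    """A small synthetic signature set (4 up + 4 down genes per subtype)."""
    sigs = {}
    for s in SUBTYPES:
        rows = [
            {"gene_id": f"{s}_UP{i}", "direction": "up", "cm1": 1.0} for i in range(4)
        ] + [
            {"gene_id": f"{s}_DN{i}", "direction": "down", "cm1": -1.0} for i in range(4)
        ]
        sigs[s] = pd.DataFrame(rows)
    return SignatureSet(sigs)


def simulate_cell_lines(
    n_lines: int = 26,
    n_drugs: int = 8,
    planted_rho: Optional[dict] = None,
    subtype_split: Sequence[int] = (6, 8, 4, 6),
    signature: Optional[SignatureSet] = None,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, SimulationTruth]:
    """Cell-line expression and ln(IC50) with planted score-drug Spearman rho.

    A latent signature score per line and each drug's ln(IC50) are joined
    by a Gaussian copula whose Pearson parameter r = 2 sin(pi rho / 6)
    yields the requested population Spearman rho; |rho| = 1 uses the
    comonotone coupling exactly.  The default subtype split 6/8/4/6 over
    26 lines leaves two lines unassigned, mirroring a realistic panel in
    which the classifier cannot place every line.
    """
    if sum(subtype_split) > n_lines:
        raise ValueError("subtype split exceeds n_lines")
    rng = np.random.default_rng(seed)
    drugs = [f"drug_{i:02d}" for i in range(n_drugs)]
    if planted_rho is None:
        cycle = [0.6, -0.6, 0.0]
        planted_rho = {d: cycle[i % 3] for i, d in enumerate(drugs)}
    if any(abs(r) > 1 for r in planted_rho.values()):
        raise ValueError("|planted_rho| must be <= 1")

    lines = [f"LINE{i:03d}" for i in range(n_lines)]
    lab = []
    for s, k in zip(SUBTYPES, subtype_split):
        lab += [s] * k
    lab += ["unassigned"] * (n_lines - len(lab))
    labels = pd.Series(lab, index=lines, name="label")

    z = rng.normal(0.0, 1.0, n_lines)
    ic50 = {}
    for d in drugs:
        rho = planted_rho.get(d, 0.0)
        if abs(rho) == 1.0:
            ic50[d] = np.sign(rho) * z
            continue
        r = 2.0 * np.sin(np.pi * rho / 6.0)
        eps = rng.normal(0.0, 1.0, n_lines)
        ic50[d] = rng.normal(2.0, 0.5) + r * z + np.sqrt(1.0 - r ** 2) * eps
    ic50 = pd.DataFrame(ic50, index=lines)

    if signature is None:
        signature = default_signature(seed)
    cols = {}
    for s in signature.subtypes:
        df = signature.signatures[s]
        for _, row in df.iterrows():
            sign = -1.0 if row["direction"] == "down" else 1.0
            cols[row["gene_id"]] = sign * z + rng.normal(0.0, noise_sd, n_lines)
    expr = pd.DataFrame(cols, index=lines)

    truth = SimulationTruth(
        seed=seed,
        config={"n_lines": n_lines, "n_drugs": n_drugs, "noise_sd": noise_sd,
                "subtype_split": list(subtype_split)},
        drug_rho=dict(planted_rho),
        labels=labels,
        size_factors=None,
    )
    truth.config["latent_score"] = [float(v) for v in z]
    return expr, ic50, labels, truth
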