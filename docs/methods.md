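# Methods

This note records the models, estimators, defaults and numerical
choices behind `tspsig`, in the order the pipeline runs, together with
what the synthetic benchmarks do and do not establish.

## Single-cell preprocessing

**Filtering.** Genes are retained by biotype (default `protein_coding`),
by symbol prefix (default exclusions `MT-`, `RPL`, `RPS` — there is no
canonical published list of mitochondrial/ribosomal symbols, so the
prefix rule is configurable), and by detection in at least `min_cells`
cells (default 3). Cells need at least `min_genes` detected genes
(default 200) and, when an annotation is supplied, a matching label such
as `"Cancer Epithelial"`. Both filters are idempotent and the thresholds
are deliberate defaults, not values inferred from any particular data
set.

**Size factors.** Per-cell scaling factors use pooling-deconvolution:
cells are placed on a ring ordered by library size (ties broken by cell
id so the estimate is invariant to input order), pools of sizes
{21, 41, 61, 81, 101} (capped at the cell count) are summed at every
ring position, and each pooled profile is scaled against the average
cell profile by a median ratio over expressed genes. Each pool
contributes one linear equation in its members' factors; the
overdetermined system, plus per-cell library-size equations at weight
0.01 to anchor the scale, is solved with sparse least squares (LSMR)
and rescaled to mean 1. Pooling before taking ratios is what makes the
median stable under the zero inflation of UMI counts. If any solved
factor is non-positive the estimator falls back to library-size factors
and flags it — never silent clipping. No clustering pre-step is used:
the intended input is a single annotated tumor-cell population.

**Expression scale.** Downstream modules consume
`log2(count/factor + 1)`. One log-like, variance-stabilized scale is
used everywhere so that CM1 scores, centroid correlations and entropy
estimates are comparable across modules.

## Subtype assignment

Nearest-centroid by correlation: Pearson by default (log-scale input),
Spearman selectable. The centroid matrix is a user input — the panel of
genes it covers defines the shared-gene space (minimum 20 by default).
A unit is labeled with the arg-max subtype only when that correlation is
positive; exact ties go to the first subtype in column order with a
warning (deterministic rather than arbitrary), and zero-variance units
are flagged `unassigned` with an undefined-correlation marker. No
significance filter is applied to the winning correlation.

## CM1 marker selection

CM1ᵢ = (x̄ᵢ − ȳᵢ) / (1 + (max{yᵢ} − min{yᵢ})). The denominator's range
is taken over individual out-of-subtype **cells** (default); reading it
over per-subtype means instead is selectable via `range_over`, since
the two readings differ on heterogeneous data. The +1 guards against
division by zero and means the score is bounded by the mean difference.
CM1 is invariant to adding a constant to all expression values and
flips sign under mirrored group roles with equal ranges.

Selection takes the top and bottom k (default 4) of the descending CM1
ranking, ties broken by lexicographic gene id. A sign guard enforces
that "up" genes have CM1 > 0 and "down" genes CM1 < 0; violating
candidates are dropped with a warning, so lists may be shorter than 2k —
a gene in the bottom four with non-negative CM1 is simply not
down-regulated. Genes appearing in two or more subtypes' candidate
lists are removed from all lists, making signatures pairwise disjoint;
the operation is independent of subtype processing order. Cells labeled
`unassigned` are excluded from both the in- and out-group.

## Representativeness

Per-gene metrics across cells: mean expression; plug-in Shannon entropy
of a 10-bin equal-width histogram spanning the gene's observed range
(constant gene → 0 bits; the estimate is bounded by log2 bins and is
invariant to affine rescaling because the bins are recomputed); and
mean absolute pairwise correlation (Spearman default) within the
signature set, against equally sized seeded random background sets.
Group differences use the two-sided Wilcoxon rank-sum test — exact for
small tie-free samples, normal approximation with tie correction
otherwise; "background" is all retained genes minus all signature
genes, and the default comparison pools all signatures (a per-subtype
mode is available through the per-signature gene lists).

## Survival validation

**Risk score.** How a multi-gene signature becomes one number per
patient is genuinely open; the default is the signed z-score mean
(per-gene z-scores, down-regulated genes negated), with unsigned mean
and first-principal-component modes selectable. Every stratification
output records the mode used.

**Cutpoint.** Maximally selected rank statistic: every unique score
value is a candidate threshold (high = score strictly above); splits
leaving less than `minprop` (default 0.1) of samples in either group
are inadmissible; the threshold maximizing the absolute standardized
log-rank statistic wins, ties to the smallest threshold. The reported
`p_naive` is the plain log-rank p of the optimized split — the quantity
K-M panels usually display. Because the threshold maximizes exactly
that statistic, `p_naive` is strongly anti-conservative under the null:
in the package's own null simulation (n = 100, 20% censoring) it
rejects at the 5% level roughly 45% of the time, while the same
log-rank test at a *fixed* median split rejects at 5.0%. Treat
`p_naive` as descriptive; no selection-adjusted p is provided.

**Log-rank and KM.** The two-group log-rank statistic is computed from
observed/expected event counts with the hypergeometric variance
(needed in vectorizable form for the cutpoint scan; cross-checked
against lifelines in the tests). Kaplan-Meier curves come from
lifelines.

**Cox models.** lifelines `CoxPHFitter`: Efron tie handling, Wald CIs
and p-values, Breslow baseline cumulative hazard. Non-convergence
(monotone likelihood/separation) is re-raised with the covariate list.
The summary table reports univariate and multivariate HR / 95% CI / p
per covariate, with stage encoded as III vs I/II and therapies as
binary indicators. Raw p-values only — no multiplicity adjustment.

**Nomogram.** Points(cov, v) = 100·β·(v − ref)/M where ref is the
low-risk end of the covariate's clinical range and M = max |β|·range;
the largest-span covariate covers exactly 0–100 points. Total points
map to predicted survival via S(t|x) = S₀(t)^exp(lp − lp_mean), with S₀
the baseline survival at covariate means; horizons beyond follow-up are
extrapolated flat with a warning. Predicted survival is monotone
nonincreasing in total points by construction.

**Calibration.** Samples binned by predicted survival at the horizon
(quantile bins; adjacent bins under 10 samples merged); observed value
is the within-bin KM estimate with its 95% CI.

**Time-dependent AUC.** Cumulative/dynamic AUC with inverse-probability-
of-censoring weights (scikit-survival). Without censoring it reduces
exactly to the Wilcoxon AUC of "event by horizon" vs "survived past
horizon", which the tests assert.

## Drug sensitivity

Lines are scored with the same signed z-mean as the survival module
(one score definition across modules), split at the median (ties at the
median go low), and each drug's ln(IC50) compared between groups by a
two-sided Mann-Whitney test — exact enumeration for total n ≤ 12 and
for other small tie-free samples, asymptotic otherwise. Direction is
sign(median high − median low): negative means the high-expression
group is more sensitive, matching the sign convention of the Spearman
correlation between score and ln(IC50) (average ranks for ties,
t-approximation p). Tests are per compound, unadjusted; drugs with
fewer than 3 non-missing lines, or fewer than 2 per group, are skipped
with the recorded reason.

## Synthetic data

**Counts.** Genes get log-normal baseline means (meanlog ln 0.3,
sdlog 1.2 → ≈600 UMI per cell at 2000 genes), cells get log-normal size
factors (sdlog 0.25 default), and counts are gamma-Poisson, i.e.
negative binomial with variance m + φm² (φ the dispersion). Each
subtype's markers are shifted ±log_fc (log2 units) in that subtype
only. Marker genes are drawn from genes with baseline mean ≥ 1
UMI/cell: a "down-regulated" gene whose baseline is near zero is
unobservable in principle, and real signature panels consist of
well-detected genes. Centroids are the true per-subtype mean
log-expression over the marker panel — the discriminative genes, as in
nearest-centroid classifiers. A separate generator draws units directly
as centroid + Gaussian noise (σ expressed as a fraction of the
centroid's across-gene SD) for classifier benchmarking.

**Survival.** Weibull baseline (shape 1.2, scale 72 months) with a
proportional-hazards linear predictor over centered covariates
(age N(58,10), tumor size N(25,10) mm, stage III/chemo/hormone
Bernoulli(0.3/0.6/0.3), score N(0,1)). Event times by inverse
transform; exponential censoring with the rate tuned by bisection
against the drawn event times to hit the target fraction
(deterministic given the seed; a warning reports unattainable
targets). A threshold mode replaces the linear score term with a step
at a chosen score quantile, planting a true change-point for
cutpoint-recovery experiments. `simulate_bulk_cohort` spreads the
latent score over signature genes (up = +score + noise, down =
−score + noise) plus pure-noise background genes.

**Cell lines.** A latent per-line score and each drug's ln(IC50) are
joined by a Gaussian copula with Pearson parameter r = 2 sin(πρ/6),
which yields the requested population Spearman ρ; |ρ| = 1 uses the
comonotone coupling exactly. Default panel: 26 lines split 6/8/4/6
across BL1/BL2/LAR/M with two lines left unassigned, the realistic
shape of a classifier-labeled panel.

**What passing tests show — and don't.** The generators plant exactly
the structure the estimators assume: NB counts without batch effects,
doublets or ambient RNA; proportional hazards with independent
censoring; monotone drug associations. Recovery on these benchmarks
demonstrates correctness of the implementations under their stated
assumptions, not robustness to the violations real data exhibit
(batch structure, non-PH hazards, informative censoring, heavy-tailed
IC50 panels).

## Problem sizes and numerical choices

Benchmarks run at: marker recovery 4×300 cells × 2000 genes × 20 seeds;
size-factor recovery 500 cells (the DE-free max-relative-error check
uses 8000 genes ≈ 13k UMI/cell, comparable to the ~12.6k-gene matrices
this method targets, because per-cell factor information at 2000
low-depth genes is itself above the 10% band); Cox recovery 200
replicates at n = 500; cutpoint null 400 replicates at n = 100;
rank-sum calibration 1000 replicates. These sizes give Monte-Carlo
error comfortably below the asserted margins while keeping the full
suite around a minute.

LSMR is run to atol = btol = 1e-12; CM1 is exact vectorized arithmetic
(oracle agreement ~1e-16); Newton convergence and tie handling inside
Cox fits follow lifelines defaults; all tie-breaks (ranking,
classification, median split) are deterministic and documented above.
Degenerate inputs (constant vectors, empty filter results, all-tied
groups, horizons beyond follow-up) raise explicit errors or return the
documented conventions (p = 1 for vacuous tests, flat extrapolation
with warning).

## Known limitations

- The centroid matrix must be supplied; the package does not re-derive
  published TNBC subtype centroids.
- `p_naive` after cutpoint optimization is anti-conservative (above);
  downstream Cox tables treat the dichotomized group as a covariate and
  inherit that optimism.
- The denominator-range reading of CM1 (cells vs subtype means) changes
  scores on heterogeneous data; only the default is benchmarked.
- Enrichment analysis, doublet detection, batch correction and
  competing-risks models are out of scope.
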