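# tspsig

Subtype-specific prognosis signatures for triple-negative breast cancer
(TNBC), discovered from single-cell RNA-seq and validated on bulk
cohorts.

TNBC carries no ER/PR/HER2 targets and splits into four molecular
subtypes (TNBCtype-4: BL1, BL2, LAR, M) with different biology and
outcomes, yet subtype-specific prognostic gene signatures are hard to
obtain from bulk data, which averages over tumor and microenvironment.
`tspsig` implements the single-cell route: work only with annotated
cancer-epithelial cells, assign each cell a subtype, and rank genes by
how cleanly they separate one subtype from the rest. The package is
aimed at computational biologists who want the full pipeline — or any
single stage of it — as tested, scriptable Python.

## The method

1. **QC + normalization** (`sc_preprocess`): keep protein-coding genes,
   drop mitochondrial/ribosomal genes (`MT-`/`RPL`/`RPS` prefixes),
   drop low-coverage genes and cells; estimate per-cell size factors by
   pooling-deconvolution (sum cells into ring pools, scale each pooled
   profile against the average profile, solve the linear system by least
   squares) and form `log2(count/factor + 1)`.
2. **Subtype assignment** (`subtype_classifier`): correlate each cell
   (or bulk sample, or cell line) with user-supplied subtype centroids;
   assign the subtype of highest positive correlation, else
   `unassigned`.
3. **Marker selection** (`cm1_signatures`): per subtype, score every
   gene with the CM1 statistic

   CM1ᵢ = (x̄ᵢ − ȳᵢ) / (1 + (max{yᵢ} − min{yᵢ}))

   where x̄ᵢ is gene *i*'s mean expression inside the subtype, ȳᵢ its
   mean outside, and max{yᵢ}/min{yᵢ} the extreme values outside. Take
   the top *k* (up) and bottom *k* (down, default k = 4) of the ranking,
   then remove genes appearing in two or more subtypes' candidate lists
   to get disjoint signatures.
4. **Representativeness** (`representativeness`): compare signature vs
   background genes on mean expression, histogram Shannon entropy, and
   mean absolute inter-gene correlation (two-sided rank-sum tests).
5. **Survival validation** (`survival_eval`): per-sample risk score
   (signed z-score mean over signature genes), maximally selected
   rank-statistic cutpoint, Kaplan-Meier + log-rank, uni-/multivariate
   Cox (Efron ties), nomogram points table, calibration curve, and
   IPCW cumulative/dynamic AUC at 3/5 years.
6. **Drug sensitivity** (`drug_sensitivity`): median-split Mann-Whitney
   tests and Spearman correlations between signature score and ln(IC50)
   across subtype-labeled cell lines.
7. **Synthetic data** (`synthetic_data`): negative-binomial UMI counts
   with planted markers and size factors, Weibull proportional-hazards
   cohorts, and copula-coupled cell-line/IC50 panels — every generator
   records its ground truth, so the whole pipeline is testable without
   any external download.

## Worked example

```python
import tspsig as T

# synthetic experiment: 4 subtypes x 300 cells, 2000 genes,
# 4 up + 4 down planted markers per subtype at log2 fold change 2
adata, centroids, truth = T.simulate_counts(n_cells_per_subtype=300, seed=0)
filtered, factors, expr = T.preprocess(adata, keep_label="Cancer Epithelial")
labels = T.classify(expr, centroids, min_shared_genes=5)
sigs, cm1_table = T.discover_signatures(expr, labels,
                                        subtypes=["BL1", "BL2", "LAR", "M"])

sig = sigs.signatures["BL1"]
bulk_expr, clinical, _ = T.simulate_bulk_cohort(sig, n=150, beta_score=1.1, seed=1)
strat = T.risk_stratify(bulk_expr, clinical, sig)
```

Output of this run:

```
retained 1200 cells x 2000 genes
label counts: LAR 321, M 298, BL1 292, BL2 289
BL1/BL2/LAR/M signatures: 8 genes each, planted-marker recall 1.00
cutpoint 0.532  high n=42  low n=108
log-rank p = 1.08e-17   HR(high vs low) = 6.65
3-year cumulative/dynamic AUC = 0.812
```

Reading: QC kept all 1200 simulated tumor cells; centroid correlation
recovered the subtype of ~98% of cells; CM1 selection returned exactly
the 32 planted marker genes; on a simulated 150-patient bulk cohort the
BL1 signature's risk score split patients into a 42-patient high-risk
and 108-patient low-risk group with a hazard ratio of 6.7 and a 3-year
AUC of 0.81. (The log-rank p of an optimized split is anti-conservative
by construction — see `docs/methods.md`.)

The same stages are exposed as a CLI (`tspsig simulate|preprocess|
classify|signatures|represent|evaluate|drugs`) reading and writing
MTX/CSV/JSON.

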