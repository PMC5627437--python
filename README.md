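# favsig

Combined gene-expression signatures of response to antimetabolite
chemotherapies (5-FU, Gemcitabine and kin), built from favorability-score
discretization.

Single target-enzyme markers (TYMS for 5-FU, RRM1/RRM2 for Gemcitabine)
separate responders from non-responders only weakly. `favsig` implements the
alternative: screen the whole transcriptome for survival- or
IC-50-associated genes, discretize their expression into per-(gene, sample)
**favorability scores**, and cluster the score matrix into response
subgroups. The package is aimed at computational biologists analysing
treated tumor cohorts (expression + progression-free survival) or
drug-sensitivity panels (expression + IC-50), and ships a synthetic-data
module so the entire pipeline is testable with known ground truth.

## The method

For gene *i* with expression *E<sub>ij</sub>* in sample *j*, let
*med<sub>i</sub>* and *s<sub>i</sub>* be the per-gene median and SD. The
favorability score is

```
F_ij = +1   if E_ij >= med_i + s_i/2  and the anchor is favorable
     = -1   if E_ij >= med_i + s_i/2  and the anchor is unfavorable
     =  0   otherwise
```

where the anchor is, for tumors, the gene's association with
progression-free survival (univariate Cox proportional hazards: favorable
iff the log-hazard coefficient β < 0, i.e. HR = e^β < 1), and for cell
lines the sign of the Kendall tau between expression and IC-50 (favorable
iff τ < 0: high expression tracks sensitivity). Genes enter the score
matrix only after a screen (Cox p < 0.05, or |τ| > 0.2 with p ≤ 0.01 after
a CV ≤ 0.05 filter) and, for tumors, after removing genes associated with
clinical confounders (Wilcoxon rank-sum for binary covariates such as TP53
mutation; Spearman for stage, age, grade, nodal status). k-means (k = 2) on
the rows of **F** yields a favorable-signature and an unfavorable-signature
subgroup; their progression-free survival is compared with a binary Cox
model (likelihood-ratio p, HR oriented unfavorable vs favorable), or their
IC-50 with a two-sided Wilcoxon test. Cross-validation re-derives
everything on training folds and assigns held-out samples to the nearest
training centroid. Companion analyses: a single-gene optimal-cutpoint
baseline (maximally selected log-rank statistic), Fisher's-exact gene-set
enrichment of the signatures, and cell-phenotype correlates of sensitivity
with the volume-corrected growth rate kg = V₀·k_p/ln 2.

## Worked example

```python
from favsig import TumorSimConfig, simulate_tumor_cohort, FavorabilityStratifier

expr, surv, truth = simulate_tumor_cohort(TumorSimConfig(seed=11))
model = FavorabilityStratifier(
    binary_covariates=("tp53_mutant",),
    ordinal_or_continuous_covariates=("stage",),
    random_state=0,
).fit(expr.values.T, surv)          # samples x genes, survival table

print(model.funnel_)
print(f"Cox p = {model.comparison_.p_value:.3g}, "
      f"HR = {model.comparison_.hazard_ratio:.2f}")
```

prints

```
{'input_genes': 1000, 'screen_hits': 93, 'after_confounder_filter': 88, 'signature_genes': 88}
Cox p = 3.41e-07, HR = 2.67
```

Read: of 1000 simulated genes, 93 passed the survival screen, 88 survived
the TP53/stage confounder filter and form the signature; the two k-means
subgroups of the favorability matrix differ strongly in progression-free
survival (the unfavorable-signature group progresses ~2.7× faster). The
same estimator's `predict` assigns new samples by nearest training
centroid, which is exactly what `favsig.cross_validate` uses per fold.

A command-line layer wraps the workflows
(`favsig simulate|tumor|cellline|phenotype|enrich`; see `favsig --help`).

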