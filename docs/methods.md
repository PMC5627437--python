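# Methods

## The model

The pipeline treats drug response as a latent property of a sample that is
reflected jointly in many genes rather than in any single marker. Its
stages, and the statistical model behind each:

**Screening.** For tumors, each gene is fit independently in a univariate
Cox proportional-hazards model of progression-free survival on
standardized expression (per-SD log-hazard coefficients). Fits maximize
the Efron-tie-corrected partial likelihood with a vectorized
Newton–Raphson that solves all genes simultaneously; agreement with
`lifelines` is asserted in the test suite to |Δβ| < 1e-5 on tied and
untied data. Wald p-values are the default (likelihood-ratio by option);
genes with p < α = 0.05 are retained, deliberately without any
multiple-testing correction — the screen is a recall-oriented funnel, and
the output metadata says so explicitly. For cell lines the screen is the
Kendall tau-b between expression and one drug's IC-50 (exact null
enumeration for n ≤ 8 tie-free pairs, normal approximation otherwise),
retaining |τ| > 0.2 with p ≤ 0.01 after removing genes with coefficient of
variation ≤ 0.05. |τ| rather than one-sided τ: both sensitivity and
resistance markers are wanted.

**Confounder filter (tumor branch).** A retained gene is dropped when its
expression differs between levels of a binary clinical covariate
(two-sided Wilcoxon rank-sum) or correlates with an ordinal/continuous one
(Spearman), each at a per-test α = 0.05, uncorrected. The filter is
deliberately aggressive in that direction: its job is to guarantee the
signature adds information beyond stage, age, grade, nodal status and TP53
state, at the cost of discarding some true hazard genes (expected null
loss 1 − 0.95^k for k covariates).

**Favorability discretization.** A gene scores nonzero in a sample only
when expression is at or above the gene's median + SD/2 (sample SD, n−1);
the sign comes from the anchor. "High expression co-occurs with good
outcome" admits two readings, both implemented behind `mode`:
`gene_direction` (default) signs every high cell of a gene by that gene's
screen direction, producing column-coherent favorable/unfavorable gene
blocks and avoiding any per-sample use of outcome; `patient_class` signs
cells by the sample's own outcome class (event before the cohort's median
event time = poor; event-free to that median = good; censored earlier =
neutral; for cell lines, IC-50 at or below the lower quartile = sensitive,
at or above the upper = resistant). `gene_direction` is the default
because clustering samples on labels derived from their own survival is
circular when the clusters are then tested against survival. The ≥
boundary convention and the quartile classing are fixed choices; quantiles
use linear (type-7) interpolation.

**Stratification.** k-means (k = 2, 50 restarts, seeded) on the rows of
the score matrix; groups are named by mean favorability. Subgroup survival
is compared by a binary-covariate Cox fit reporting the likelihood-ratio p
and the HR oriented unfavorable-vs-favorable; subgroup IC-50 by a
two-sided Wilcoxon rank-sum. If the two groups are completely separated in
event space the unpenalized fit can stall; it is retried with a small
ridge penalty (0.01) and flagged unstable.

**Cross-validation.** k-fold (default 5, shuffled, seeded). Screen,
confounder filter, per-gene thresholds, directions and k-means centroids
are estimated on training folds only; held-out samples are scored with the
frozen thresholds and assigned to the nearest training centroid. Per-fold
train and test subgroup p-values are reported with their median and SD.
The test-assignment rule (nearest centroid) is the one genuinely open
design point; it is the natural frozen-model analogue of the k-means step.

**Single-gene baseline.** The optimal cutpoint scans every distinct
observed expression value leaving at least 10% of samples on each side and
maximizes the two-sample log-rank statistic. The maximally selected
statistic is anti-conservative as a test; no correction is applied because
the procedure serves as the baseline the combined signature is compared
against, and the package documents rather than repairs that bias.

**Enrichment.** One-sided Fisher's exact test (hypergeometric tail) of the
favorable and unfavorable signatures separately against GMT gene sets,
over a background universe defaulting to the genes that entered the screen
(conditioning on testable genes), raw p < 0.05.

**Phenotype correlates.** Sensitivity is −log10(IC-50); all correlations
are Spearman, so the log base is immaterial (asserted by test). Per-trait
BH q-values across the drug family, significance at q < 0.05; the CORE
(consumption/release) sign convention is positive = released. The growth
rate corrects proliferation for cell size: with linear volume growth and
division at doubled volume, V₀ = T_d·k_g and T_d = ln 2/k_p give
k_g = V₀·k_p/ln 2 (volume/day). Drug similarity is the pairwise-complete
Pearson correlation of raw IC-50 profiles with average-linkage clustering
on 1 − r.

## The synthetic-data generator

The generators exist so every stage is testable against known truth; they
emulate the statistical structure of treated-cohort data, not its
technical artifacts.

*Tumor cohorts.* Expression is Gaussian on the log scale (per-gene mean
U(2,12), SD U(0.5,2) around standardized latents). Planted genes form one
co-regulated "program" per direction: each member loads √0.5 on a shared
factor. Samples belong to one of two planted classes (favorable- vs
unfavorable-signature, Bernoulli ½) whose program means differ by
`subgroup_separation` = 2 latent SD — the generator plants an actual
subgroup structure, mirroring the visibly distinct sample blocks the
method is designed to find, rather than a continuum. The per-sample
log-hazard is `effect_log_hazard` (default 0.5) times the standardized
combined score (unfavorable-program sum minus favorable-program sum); for
independent genes this standardization is exactly the √n_planted divisor,
and it keeps the effect parameter interpretable as per-SD log-hazard under
the factor structure. Event times are exponential PH (Weibull by option)
with baseline 1/500 events/day; censoring is independent exponential at
1/1000/day, giving ~⅓ censoring in a null cohort
(rate_c/(rate_c+rate_e)). Confounded genes are shifted 1 latent SD between
TP53 levels and carry no hazard effect, so filter correctness is pure
recall/rejection. Covariates are independent of everything else
(tp53 ~ Bern(0.4), ordinal stage/grade/nodal 1–4, age ~ N(65, 10)).

*Cell-line panels.* log IC-50 ~ N(2,1); signal genes are Gaussian-copula
transforms with latent correlation r = sin(π·τ*/2), which makes the
expected Kendall tau equal the target τ* in closed form (checked by
simulation); signs alternate between resistance and sensitivity markers.
Gene means/SDs keep CV above the 0.05 filter so the filter's effect is
exercised separately.

*Phenotype panels.* log V₀ and log k_p are bivariate normal with
correlation −0.5 (big cells divide slowly), scaled to ~2000 fL and
~0.5/day. The common sensitivity axis is (log k_p − log V₀)/√(2·1.5),
which has exactly zero correlation with log k_g = log V₀ + log k_p under
equal latent variances — so the proliferation-vs-growth-rate contrast is a
structural property of the generator, not a tuned accident. Drugs load 0.8
on that axis, 1.0 on one of three family factors, 0.5 private noise
(within-family IC-50 correlation ≈ 0.87, cross-family ≈ 0.34); the family
is encoded in the drug id. One CORE metabolite (phosphocholine release)
loads negatively on family 0's factor (release ↔ resistance), one tracks a
single drug's private noise, one is null.

What the generators deliberately omit: count noise and library-size
effects (a raw-count mode exists only to exercise the low-count filter),
batch structure, tumor purity, covariates correlated with outcome,
non-proportional hazards, and missingness mechanisms. Passing tests
therefore demonstrate the machinery's correctness and calibration under
the stated model, not robustness to real-data pathologies.

## Problem sizes and numeric choices

Simulation-based checks use cohorts of n = 200 (screens over 1000 genes;
n = 100 for calibration and confounder checks), 20 replicate seeds for
subgroup/drug-family recovery, 10 for cross-validated null honesty, and
60-line × 17-drug phenotype panels — sizes at which every property has
comfortable statistical margin while a full run stays in the minutes
range. The cross-validation significance check uses a strong planted
program (effect 1.0/SD, subgroup HR ≈ 5, the regime of the cohorts the
method targets): a power analysis shows that at effect 0.5/SD a 40-sample
test fold has ≈0.43 power, so no implementation could make held-out folds
reliably significant there, while the screen-recall checks keep 0.5/SD.
The confounder false-removal rate is pooled over 20 seeds because the
shared program factor removes genes in correlated blocks (per-seed rates
0–0.5 around a ~0.09 mean).

Newton iterations stop at |Δβ| < 1e-9 with steps clipped to ±5; constant
genes are flagged (p = 1) rather than fit; non-convergent genes are
excluded from hit lists with a log entry. k-means uses 50 restarts and a
fixed seed; a score matrix with fewer distinct rows than k is flagged
non-separable and split trivially rather than clustered. Ties in IC-50 and
expression are handled by tau-b and average ranks throughout.

## Known limitations

- The screen is marginal: correlated genes enter or leave the signature
  together, and no multivariate or penalized survival model is offered.
- `patient_class` scoring cannot be applied to unseen samples (their
  outcome class is the label being predicted); prediction requires
  `gene_direction` mode.
- The optimal-cutpoint p-value is anti-conservative by construction.
- Enrichment p-values depend strongly on the chosen universe; with the
  default (screen input) universe they are not comparable to tools that
  use a whole-genome background.
- The growth-rate identity assumes linear volume growth between divisions
  and equal daughter volumes.
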