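# Methods

This note documents the models, the numerical choices, and what the
synthetic-data generator does and does not emulate.

## Study design and labels

A sample is MET if distant metastasis occurred within 3 years of treatment,
non-MET if metastasis-free beyond that window. The pipeline assumes two
training cohorts from different sites (used jointly for marker and panel
selection), one testing cohort (model comparison), and survival follow-up
for stratification. Expression enters all risk models as
`log10(normalised count + 1)`; deconvolution uses the normalised linear
scale, because the mixture model is linear in expression.

## Marker screen

Counts are normalised by median-of-ratios size factors (geometric-mean
reference over genes with all-positive counts). Differential expression is
a per-gene OLS of the normalised-log expression on the MET indicator plus
optional covariates (relapse by default in cohort 1, none in cohort 2), a
two-sided t-test on the group coefficient, and Benjamini-Hochberg
adjustment. This linear-model surrogate replaces a negative-binomial Wald
test deliberately: the screen's scientific content is its thresholds and
the cross-cohort intersection rule, and the per-gene linear model supports
covariate adjustment with no external tooling. Fold-change is computed on
normalised counts with a pseudo-count of 1, so all-zero genes are well
defined. Genes fitted exactly (zero residual to round-off) are assigned
p = 1 rather than letting a 0/0 t-ratio produce noise.

Thresholds follow a two-sample t-test power analysis via the noncentral-t
distribution (ncp = d·√(n₁n₂/(n₁+n₂)), two-sided): at the conventional
large effect d = 0.8, cohort 1 (39/38) has 88.7% power at α = .025 and
98.6% at α = .2 — hence p < .025 and FDR < .2 there — and the smaller
second screen uses p < .05 (87.3% power at the testing cohort's 23/47).

## Pareto panel selection

Cohort-swap objectives avoid merging cohorts: fitting on one cohort and
validating on the other (and vice versa) yields an AUC pair per panel, and
panels are compared by Pareto dominance (≥ on both, > on one). Exactly
tied objective pairs are all retained on the frontier: nothing before
test-cohort validation can distinguish them.

- Exhaustive enumeration is plain lexicographic k-combinations (traversal
  order does not affect the result set); a budget guard (500k subsets)
  redirects larger problems to the GA.
- The genetic search is NSGA-II-style (fast nondominated sort, crowding
  distance, binary tournament, uniform crossover at rate 0.9, per-bit
  mutation at rate 1/|pool|), with offspring repaired into the cardinality
  range [k_min, k_max] by random bit add/drop. Defaults: population 200,
  100 generations; these are conventional values for pools of tens of
  genes, and the frontier is taken over the archive of *all* evaluated
  subsets, so extra search can only add candidates. Seeded and
  deterministic.
- Frontier quality is measured by dominated hypervolume with reference
  point (0, 0), which the test suite compares against the exhaustive
  frontier on pools small enough to enumerate.
- The degenerate case (constant expression in a subset) scores AUC 0.5
  with a warning rather than failing.
- The LASSO baseline is L1-penalised logistic regression with the penalty
  chosen by cross-validated AUC; per-cohort gene mean-centering before
  pooling acts as the location-shift batch surrogate.

## Linear risk scores

The "linear prediction model" is OLS of the 0/1 label on the features,
followed by the affine rescaling s' = (s − mean_nonMET)/(mean_MET −
mean_nonMET). OLS plus this calibration is the unique choice that makes
training group means exactly 0 and 1 (a logistic fit would not); the
rescaling is well defined because the OLS fitted values' group-mean gap is
nonnegative by construction, and a zero gap is the degenerate constant
score. The operating cutoff maximises Youden's J over midpoints between
adjacent distinct scores, ties broken toward the higher threshold.

`bootstrap_compare` repeats a stratified 70/30 split (at least 2 training
and 2 validation samples per stratum) `n_reps = 200` times, refitting the
clinical-only and clinical+RNA models on each training split with the RNA
score itself frozen — matching the single RNA term in the combined
formula — and records both validation AUCs and the replicate IDI. IDI is
defined on risks in [0, 1], so scores are mapped through a univariate
logistic calibration fitted on the training fold (near-unpenalised,
C = 1e6). AUC samples are compared with a two-sided Mann-Whitney U test,
IDIs with a Wilcoxon signed-rank test against zero. The final model
averages the replicate coefficient vectors and recalibrates on the full
cohort.

## Variance-weighted deconvolution

The objective divides each gene's squared residual by the
proportion-weighted reference variance Σ_j P_j σ²_ij (floored at
ε = 10⁻⁶·max σ² to prevent division by zero), so intrinsically variable
genes are penalised less. Reference construction ranks genes per cell type
by two-sided Welch t-test p-value (in-type vs rest; zero-variance
degenerate genes rank last) and takes the per-type top-G union; G is
chosen to minimise the condition number of the resulting mean matrix,
smallest G on ties.

The per-sample scaling factor s is initialised so the scaled bulk total
matches the equal-proportion reference total, and — by default — refined
during optimisation by a closed-form weighted least-squares step. Freezing
s at the totals-matching value is available (`optimise_scale=False`) but
not the default: for a non-uniform mixture the bulk total differs from the
equal-proportion total by O(1%), so a frozen s biases the recovered
proportions by a few 10⁻³ and breaks exact noiseless identifiability,
which the joint estimate restores (machine-precision recovery when the
mean matrix has full column rank).

The solver is layered: a particle swarm (inertia 0.7, cognitive/social
1.5, softmax reparameterisation to stay on the simplex, one particle at
the uniform mixture and one near each pure type) provides a global start;
iteratively reweighted constrained least squares (NNLS on a sum-to-one
augmented system, weights frozen per step) converges to the weighted-LS
fixed point; and a projected-gradient pass with the exact gradient
(including the denominator term IRLS ignores) finishes at a stationary
point. The returned estimate is never worse than the uniform mixture. A
plain NNLS fit is the unweighted comparison arm; the variance weighting
empirically produces fewer hard-zero proportion collapses on noisy
mixtures.

## Survival analysis

Kaplan-Meier via the product-limit estimator (cross-checked against
lifelines). The weighted log-rank statistic accumulates, per distinct
event time, the observed-minus-expected events in one group and the
hypergeometric variance with the standard ties correction; weights are 1
(log-rank), √(n at risk) (Tarone-Ware, emphasising early events), or any
callable, and the statistic (Σw(O−E))²/Σw²V is referred to χ²₁. Censoring
at an event time counts after the event. Stratification calls a sample
high-risk when its score strictly exceeds the cutoff.

## TLS quantification

The signature score is the per-sample mean of gene-wise z-scores over a
user-supplied TLS marker set (zero-variance genes contribute 0) — a
transparent surrogate for heavier pathway-activity scoring.

Spatial counting: B-cell-phenotype cells (CD20+CD45+PanCK−) are clustered
with DBSCAN (eps = 30 µm, min 5 neighbours — chosen for densely packed
lymphoid aggregates); a cluster is a TLS when it has strictly more than
100 members and ring-phenotype cells (CD20−CD45+PanCK−) cover at least
half of the angular bins of the annulus extending 50 µm beyond the
cluster's 95th-percentile radius. The composition rule (>100 cells,
surrounded) is the definition; clustering radius, ring width and angular
coverage are the operationalisation and are configurable. Valid tissue
area (mm²) is an input from upstream image QC; density is count/area.
Everything is invariant to rigid transforms of the coordinates.

## Synthetic-data generator

Defaults reproduce the target study design: cohorts of (39 MET, 38
non-MET), (13, 17) and (23, 47); 15 up- and 14 down-regulated planted
markers at |log2FC| = 1 (comfortably above the 0.5 screening threshold,
typical of a validated biomarker panel); negative-binomial counts
(variance μ + μ²·φ, φ = 0.1, a mid-range bulk RNA-seq dispersion);
gene-wise multiplicative cohort effects 2^N(0, 0.3) emulating library-prep
batch differences without assuming any correction model; log-normal
baseline means (heavy-tailed like real expression); uniform library sizes
0.5–1.5M. Clinical indicators (BMI ≥ 23, EBV ≥ 4000 copies/mL, TNM = 4,
relapse) are binary with MET-shifted log-odds (−1.0, +1.2, +1.5, +1.0 —
directions matching the combined model's signs, magnitudes of typical
epidemiological size). Survival is exponential with log-hazard linear in a
latent risk centred at 0/1 for non-/MET, censored uniformly over 120
months. Mixtures are proportion-weighted reference means with optional
variance-scaled Gaussian noise. Spatial maps plant 2-SD-truncated Gaussian
B-cell aggregates (compactness is part of what "aggregate" means; an
untruncated tail would shed stragglers no density clustering should claim)
with an adjacent annulus of ring-phenotype cells and a uniform background
(73% tumour, 25% lone CD45+, 2% B phenotype).

What the generator does **not** emulate: read-level sequencing artefacts,
gene-gene correlation structure, EBV genome features, continuous clinical
covariates, informative censoring, or realistic TLS morphology beyond
compact clusters. Passing tests therefore demonstrate correctness of the
algorithms under the declared generative model, not clinical performance
on real cohorts; headline real-data figures (e.g. a 74.2% test AUC) are
not reproducible from synthetic data and are not targets of the suite.

## Problem sizes in the test suite

Tests run the full cohort design at 1 200–2 000 genes, GA-vs-exhaustive
comparisons on 12-gene pools (1 585 enumerable subsets), deconvolution on
60-gene/4-type references, and 1 000 permutation simulations for
survival-test null calibration — sizes at which every oracle
(enumeration, brute-force pair counting, projected-gradient multi-start,
hand-computed tables) is exact and fast.
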