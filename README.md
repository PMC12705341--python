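# npcrisk

Multi-cohort metastasis-risk modelling for nasopharyngeal carcinoma (NPC).

Patients whose NPC metastasises to distant organs within three years of
treatment (MET) fare far worse than those who stay metastasis-free
(non-MET), so a pre-treatment risk score is clinically valuable. Building
one from several small RNA-seq cohorts is hard because site/batch effects
confound naive cohort merging. `npcrisk` implements a pipeline that sidesteps
batch correction entirely:

1. **Marker screening** (`npcrisk.screening`) — median-of-ratios library
   normalisation, a per-gene linear model of `log10(normalised count + 1)`
   on MET status (optionally adjusted for covariates such as relapse), BH
   false-discovery control, and intersection of the markers that pass both
   training cohorts' thresholds with concordant direction. Thresholds are
   grounded in a noncentral-*t* power analysis
   (`power_two_sample_t(39, 38, d=0.8, alpha=0.025) = 0.887`).
2. **Pareto panel selection** (`npcrisk.pareto`) — each candidate gene panel
   *S* gets two objectives: AUC(train on cohort 1 → validate on cohort 2)
   and the same with roles swapped. A panel dominates another if it is at
   least as good on both and better on one; the nondominated panels form
   the Pareto frontier. Small panel sizes are enumerated exhaustively;
   cardinality ranges use a discrete NSGA-II-style genetic algorithm over
   bitstring genomes. The frontier is then validated on an independent
   testing cohort; an L1-logistic (LASSO) baseline is included for
   comparison.
3. **Risk scores** (`npcrisk.risk`) — a statsmodels-style
   `LinearRiskScore(X, y).fit()` returning results with a `summary()`. The
   score is an OLS fit of the 0/1 label, affinely calibrated so training
   group means are exactly 0 (non-MET) and 1 (MET); the operating cutoff
   maximises Youden's J. The published five-gene score

   `RiskScore_RNA = .593×RANBP17 + .710×TRIM9 − .903×ITGAM − .803×ELOVL2 − .815×KCNJ10 + 3.190`

   and the combined clinical model

   `RiskScore = −.610×[BMI≥23] + .042×[EBV≥4000] + .873×[TNM=4] + .405×RiskScore_RNA + .388`

   are representable as `LinearRiskModel` objects. `bootstrap_compare`
   repeats a stratified 70/30 split 200 times to compare clinical-only vs
   clinical+RNA models (validation AUC, Mann-Whitney test, integrated
   discrimination improvement).
4. **Deconvolution** (`npcrisk.deconv`) — cell-type proportions *P* on the
   simplex minimising `Σ_i (bulk_i·s − Σ_j P_j μ_ij)² / (Σ_j P_j σ²_ij)`,
   a variance-weighted fit that tolerates residuals on genes that vary a
   lot within the mixture. Solved by particle swarm + iteratively
   reweighted constrained least squares + projected gradient. Reference
   construction ranks genes per cell type by t-test and picks the marker
   count minimising the condition number of the mean matrix.
5. **Survival** (`npcrisk.survival`) — Kaplan-Meier curves and weighted
   log-rank tests (log-rank and Tarone-Ware, w = √(n at risk)) for
   high/low risk groups split at the model cutoff.
6. **TLS quantification** (`npcrisk.tls`) — a tertiary-lymphoid-structure
   signature score (mean gene-wise z-score) and a spatial TLS counter:
   aggregates of >100 CD20+CD45+PanCK− B cells surrounded by
   CD20−CD45+PanCK− cells, normalised per mm² of valid tissue.
7. **Synthetic data** (`npcrisk.simulate`) — a generator reproducing the
   study design (cohorts of 39/38, 13/17 and 23/47 MET/non-MET samples,
   15 up- and 14 down-regulated planted markers, negative-binomial counts
   with per-cohort batch effects, outcome-linked clinical indicators,
   exponential survival, known-proportion mixtures, planted spatial TLS)
   so every stage is testable with known ground truth.

## Worked example

```python
from npcrisk.simulate import SimulationConfig, simulate_cohorts
from npcrisk.screening import de_screen, intersect_markers
from npcrisk.pareto import exhaustive_frontier, validate_frontier
from npcrisk.risk import LinearRiskScore, bootstrap_compare

train1, train2, test = simulate_cohorts(SimulationConfig(seed=1))[0]

r1 = de_screen(train1, lfc_min=0.5, p_max=0.025, adj_p_max=0.2,
               adjust_covariates=["relapse"])
r2 = de_screen(train2, lfc_min=0.5, p_max=0.05, adj_p_max=None)
markers = intersect_markers(r1, r2)

pool = sorted(markers.index)[:10]
frontier = exhaustive_frontier(pool, 5, train1, train2)
table = validate_frontier(frontier, train1, test)
best = table[table.best].iloc[0]

res = LinearRiskScore.from_cohort(train1, list(best.genes)).fit()
rna_scores = res.predict(test.expression(list(best.genes)).T)
report = bootstrap_compare(
    test.labels, test.clinical[["bmi_ge_23", "ebv_ge_4000", "tnm_eq_4"]],
    rna_scores, n_reps=200, seed=1,
)
print(report.summary())
```

prints (seed 1):

```
common markers: 29 (15 up, 14 down)
frontier: 111 of 252 evaluated panels
best panel ['G00054', 'G00068', 'G00170', 'G00285', 'G00493']: test AUC 1.000
bootstrap replicates        200
mean AUC clinical-only      0.780
mean AUC clinical+RNA       1.000
AUC comparison p (MW)       2.34e-76
mean IDI of RNA score       0.752
```

The screen finds exactly the 29 planted markers (15 up, 14 down in MET);
111 of the 252 five-gene panels are Pareto-nondominated (many tie at
perfect cohort-swap AUCs under this strong planted effect); and adding the
RNA score to the three clinical indicators raises the held-out AUC of the
bootstrap comparison from 0.78 to 1.00 with a strongly positive
integrated discrimination improvement — the qualitative behaviour the
pipeline is designed to detect.

A thin CLI mirrors the library: `npcrisk simulate|power|screen|pareto|
score-apply|survival|tls-detect|deconv-estimate` (see `npcrisk --help`).

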