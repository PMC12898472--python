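# Methods

This note documents the models behind `tiprog`, the parameter choices that
matter, what the synthetic-data generators do and do not emulate, and the
numerical conventions adopted where the underlying procedures are commonly
described only informally.

## Preprocessing

Cells with fewer than 200 detected genes or more than 20% mitochondrial
counts are removed, then genes detected in fewer than 3 of the surviving
cells. Mitochondrial genes are identified by a configurable ID prefix
(default `MT-`). QC is a single pass (cells first, then genes); on
realistic data this is a fixed point, but a pathological matrix in which
gene removal drops a cell below the detection threshold would need a second
pass. A per-patient QC mode is exposed in the CLI (`preprocess
--per-sample`) because merged-versus-per-sample QC is a genuine free choice;
the merged mode is the default.

Normalization is LogNormalize with scale factor 10,000 and the natural
logarithm: `x := ln(1 + 10000·x/colsum)`. Highly variable genes are ranked
by a variance-stabilized dispersion: per-gene log10 variance is regressed
on log10 mean with a degree-2 polynomial and genes are ranked by the
residual, ties broken by gene ID. This is a loess-free stand-in for the
"vst" ranking convention; it reproduces the intent (excess variance at a
given mean) with an exactly reproducible fit.

## CNV inference and malignant-cell calling

The caller works on log-normalized expression:

1. **Gene filter** — drop genes expressed in < 10 cells or with mean
   expression < 0.1 on the log2 scale (natural-log values are divided by
   ln 2).
2. **Z-score** — per gene across cells, sample standard deviation (n−1),
   clipped to [−3, 3]. Zero-variance genes carry no relative signal and are
   dropped with a warning.
3. **Smoothing** — genes sorted by (chromosome, start); each gene's value
   is the mean of up to `w = 100` genes centered on it
   (⌊(w−1)/2⌋ left, ⌊w/2⌋ right), truncated at chromosome boundaries so
   windows never span chromosomes and edge genes keep shrunken one-sided
   windows rather than being dropped. The smoothed profile is then centered
   per cell; "centering across genes" is implemented as subtraction of the
   cell's median smoothed value (config: median | mean | none).
4. **Reference adjustment** — per gene, the mean profile of the
   non-epithelial (immune + stromal) reference cells is subtracted. The
   adjustment runs after smoothing; MS/CORR are computed on the adjusted
   profile by default (`stats_on="unadjusted"` supports the other order,
   since the stage placement is a convention rather than a defined rule).
5. **Statistics** — MS is the mean squared profile value; CORR is the
   Pearson correlation with the gene-wise mean profile of the top
   `max(1, ⌈0.05·n⌉)` cells by MS (ties broken by cell ID; the top-set mean
   includes the member cell itself, so a lone top cell has CORR = 1).
   Zero-variance profiles get CORR = 0 with a warning.
6. **Call** — malignant ⇔ MS > 0.02 ∨ CORR > 0.2, strict inequalities.

Two statistical facts shape the test conditions. The null MS floor is
≈ 1/w (the variance of a window mean of unit-variance z-scores), so the
0.02 threshold sits at twice the noise floor for w = 100. The null CORR
spread scales like √(w/n_genes) because smoothing leaves ~n_genes/w
effective degrees of freedom; the 0.2 threshold is therefore only
discriminative when several thousand genes survive the filter, and the
self-inclusion of top-set cells puts a structural floor of ≈ 1/√(0.05·n)
on their CORR, which drops below 0.2 once n ≳ 500 cells. The simulator
defaults (12,000 genes, 600 cells) reflect realistic post-filter data where
both thresholds behave as intended.

## Patient-specificity and module scoring

A cluster is patient-specific when its maximum single-patient cell fraction
is ≥ 0.90 (inclusive). Module scores use binned controls: genes are ranked
by average expression (computed on a gene-ID-sorted view so results are
independent of row order), cut into `n_bins = 25` equal-frequency bins, and
for each signature gene `n_ctrl = 100` control genes are drawn without
replacement (capped at bin size) from its bin with a fixed seed; the score
is signature mean minus control-pool mean per cell. Adding a constant to
every gene of a cell therefore leaves its scores unchanged. Cells are
assigned to the argmax metaprogram, ties broken by lexicographic signature
name. Assignment uses raw scores.

## NMF metaprograms

Per sample (malignant cells only, top `nfeatures = 1000` variable genes),
the expression is z-scored per gene and negative values are truncated at
zero — the convention of consensus-metaprogram pipelines — so factors
capture above-baseline co-expression instead of absolute expression level.
V ≈ W·H is fitted by Frobenius multiplicative updates (max 500 iterations,
relative tolerance 1e−5) from a deterministic NNDSVD initialization with
zero entries filled by the matrix mean; the objective is recorded per
iteration and is non-increasing. One program per factor per rank in
k = 4…9.

A program's signature is the smallest weight-descending prefix reaching
`weight_explained = 0.8` of total weight, capped at 50 genes. Programs are
clustered on 1 − cosine similarity with average linkage and the tree is cut
at exactly `n_mp` clusters (singletons allowed); `n_mp` is a required
parameter, never inferred. Cosine similarity is computed on
signature-restricted weight vectors (weights outside a program's signature
zeroed, vectors aligned on the gene union): the dense low-weight background
shared by all factors of one sample would otherwise dominate and cluster
programs by sample of origin rather than by shared gene content. Consensus
signatures keep genes whose membership fraction across member-program
signatures is ≥ `min_confidence = 0.3`, ordered by confidence. The
cumulative-weight and membership-fraction semantics of `weight_explained`
and `min_confidence` are this package's interpretations of those
conventionally named knobs.

## Risk models

Differential expression is a two-sided Wilcoxon rank-sum per gene with
log2FC = log2(mean_a + 1) − log2(mean_b + 1) on the normalized scale and
Benjamini–Hochberg adjustment; candidates pass p_adj < 0.05 and
|log2FC| > 1 in both contrasts. Expression is standardized per gene (z)
before all Cox fitting, so coefficients are per-SD.

The univariate screen keeps genes with Wald p < 0.05 (lifelines, one fit
per gene; non-convergent genes are dropped with a warning). The L1 Cox
path (scikit-survival coxnet, 50 alphas) is cross-validated with
event-stratified, seeded 10-fold splits; held-out deviance is −2× the
Breslow partial log-likelihood of the training-fold linear predictor on the
test fold, and λ is taken at minimum mean deviance (not the 1-SE rule).
Genes with nonzero path coefficients at λ are refitted by multivariate Cox
(tiny ridge 1e−6 for numerical stability); the risk score is Σ βᵢ·zᵢ.
Samples with score strictly greater than the median are high-risk — ties
go to the low-risk group for determinism, and the cutoff plus tie rule are
stored in the model JSON.

Evaluation reports the two-sided log-rank test of the median split,
Kaplan–Meier curves, Cox HR with 95% CI for the continuous score (alone
and adjusted for user-supplied covariate columns — the adjustment set is
deliberately an input), and cumulative/dynamic time-dependent AUC at 24,
48, 72 and 96 months with inverse-probability-of-censoring weights from a
Kaplan–Meier estimate of the censoring distribution (weights 1/Ĝ(T⁻) for
cases with events by the horizon, controls still at risk). Score ties
contribute 1/2, computed so that a constant score yields exactly 0.5. The
estimator agrees with scikit-survival's `cumulative_dynamic_auc` to 1e−8
on ordinary inputs (asserted in the tests); the in-house version exists for
the exact tie convention and is the implementation of record.

## Drug screen

For each drug: log2fc = log2(mean AUC in low-risk / mean AUC in high-risk),
so positive values mean lower AUC (greater sensitivity) in high-risk
samples, and the per-risk-gene Pearson correlations with AUC are aggregated
by mean (options: median, or "any" = most negative gene). A drug passes
when log2fc > 0 and aggregate r < −0.05. How the per-gene correlations
combine is not conventionally fixed; the mean is the default and all
per-gene values are retained in the output. Because a sample correlation
between independent vectors has spread ≈ 1/√n, the −0.05 cut is only
selective on panels of thousands of samples; the planted-recovery
conditions use n = 4000.

## Synthetic data

`simulate_scrna` draws negative-binomial counts, NB(mean m, dispersion θ)
with Var = m + m²/θ and θ = 2, around log-normal per-gene base means
(median ≈ 0.5 counts), with defaults of 3 patients × 200 cells and 12,000
genes over 16 chromosomes. Per patient, 30% of cells are immune/stromal
reference cells; 30% of the epithelial cells are malignant and have the
means of planted contiguous segment genes multiplied by 2^log2_fold.
Residual per-gene patient effects are log-normal with σ = 0.05 — the
emitted matrix emulates *batch-corrected* expression, since batch
correction happens upstream of this pipeline. Planted co-expression
programs take disjoint gene sets from the upper half of base expression
(programs are made of robustly expressed genes) and disjoint active-cell
subsets of the malignant cells (program states are mutually exclusive,
matching argmax assignment semantics); active cells have program-gene means
multiplied by (1 + effect_size). A few `MT-` genes with elevated means
support the QC path.

`simulate_bulk_survival` draws log-normal expression, event times
exponential with hazard h₀·exp(Σ βᵢzᵢ) (h₀ = 0.02/month), and censoring
times uniform on (0, a) with a solved by root-finding so the expected
censoring fraction matches `censor_rate` given the drawn event times.
`simulate_drug_response` gives sensitive drugs AUC = a_d − effect·z(risk) + ε
and others AUC = a_d + ε, with a_d ~ U(0.8, 0.95) and clipping at zero.

What the generators do **not** emulate: doublets, ambient RNA, batch
effects needing correction, subclonal CNV structure, copy-number breakpoint
noise, non-proportional hazards, informative censoring, or dose-response
curve fitting. Passing recovery tests therefore demonstrates correctness of
the implementations under the stated model, not robustness to those
artifacts.

## Problem sizes and determinism

All randomness flows from explicit integer seeds (generator configs,
scorer, NMF initialization fallback, CV fold assignment); rerunning any
stage with the same seed reproduces results bit-for-bit. The recovery
studies use 600-cell/12,000-gene single-cell fixtures, six 120-cell samples
for metaprogram consensus, 300-sample cohorts with 200 genes for the risk
pipeline, 200 replicates for null calibrations, and a 4000-sample panel
for the drug screen — sizes chosen so every planted effect is comfortably
identifiable while each stage runs in seconds on one core.

## Known limitations

- The CNV caller estimates relative, smoothed dosage; it does not segment
  breakpoints, estimate integer copy number, or build subclonal trees.
- `n_mp` must be supplied; no model-selection criterion is provided.
- The DE test is the rank-sum test only; count-model alternatives are out
  of scope.
- The drug screen consumes a provided AUC table; predicting AUC from
  expression is out of scope.
- QC idempotence is guaranteed only when gene filtering does not change
  cell detection counts across the thresholds (true for realistic data).
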