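# tiprog — tumor–immune prognostics

`tiprog` implements a single-cell-to-cohort analysis chain for heterogeneous
carcinomas (its design target is triple-negative breast cancer):

1. **Malignant-cell calling from expression-inferred CNV.** Log-normalized
   expression is gene-filtered, z-scored with clipping at ±3, smoothed along
   the chromosome with a 100-gene sliding window, median-centered per cell
   and adjusted against non-epithelial (immune/stromal) reference cells.
   Each cell is summarized by its CNV signal strength
   MS = mean<sub>g</sub>(x<sub>g</sub>²) and its Pearson correlation CORR
   with the mean profile of the top-5% highest-MS cells; a cell is called
   malignant when MS > 0.02 or CORR > 0.2.
2. **Heterogeneity classification.** Epithelial subclusters are
   patient-specific when a single patient contributes ≥ 90% of their cells;
   malignant fractions are reported per cluster.
3. **Metaprogram discovery.** Per-sample multi-rank NMF (k = 4…9 on the top
   1000 variable genes of the malignant cells, multiplicative updates with
   deterministic NNDSVD-style initialization) yields gene-weight programs;
   programs are clustered by cosine similarity (average linkage, tree cut at
   nMP clusters) and consensus signatures keep genes present in ≥ 30% of the
   member programs (weight.explained = 0.8 per-program signatures).
4. **Module scoring.** Binned-control scoring: a cell's score for a gene set
   is the mean expression of the set minus the mean of seeded control genes
   drawn from matching average-expression bins; cells are assigned to their
   argmax metaprogram.
5. **Gene-signature risk models.** DE candidates (Wilcoxon rank-sum,
   BH-adjusted p < 0.05, |log₂FC| > 1, intersected across two contrasts) are
   screened by univariate Cox (p < 0.05), reduced by an L1-penalized Cox
   path with λ at minimum cross-validated partial-likelihood deviance, and
   combined into a risk score Σᵢ βᵢxᵢ from multivariate Cox coefficients.
   Patients are stratified at the median score and evaluated by
   Kaplan–Meier/log-rank, IPCW time-dependent AUC at 2/4/6/8-year horizons,
   and Cox HR of the continuous score with and without covariates.
6. **Drug-sensitivity screen.** On a samples × drugs AUC table, a drug
   passes when log₂(mean AUC low-risk / mean AUC high-risk) > 0 *and* the
   mean Pearson correlation between the model's risk genes and its AUC is
   < −0.05 (lower AUC = more sensitive).

Every stage is exercisable without external data: `tiprog.simulate`
generates negative-binomial single-cell counts with planted CNV segments
and co-expression programs, survival cohorts with log-linear hazards in
known genes, and drug-response tables with planted sensitive drugs —
all with ground-truth containers for recovery testing.

The estimator classes (`CnvCaller`, `ModuleScorer`, `MetaprogramDiscovery`,
`RiskScoreModel`) follow scikit-learn conventions (`fit`, `transform`/
`predict`, `get_params`, fitted `_` attributes); module-level functions are
thin wrappers.

## Worked example

```python
import numpy as np
from tiprog import (CnvCaller, CnvSegment, RiskScoreModel, ScSimConfig,
                    SurvSimConfig, evaluate_model, log_normalize, qc_filter,
                    simulate_bulk_survival, simulate_scrna)

# single cell: plant three 300-gene CNV segments, call malignant cells
cfg = ScSimConfig(cnv_segments=[CnvSegment("chr1", (50, 350), 0.5),
                                CnvSegment("chr3", (100, 400), -0.5),
                                CnvSegment("chr7", (0, 300), 0.5)], seed=7)
counts, cells, genes, truth = simulate_scrna(cfg)
lognorm = log_normalize(qc_filter(counts))
caller = CnvCaller().fit(lognorm, cells, genes)

# bulk survival: recover a 10-gene signature and evaluate the risk score
rng = np.random.default_rng(1)
causal = [(f"G{i:05d}", float(b)) for i, b in
          zip(rng.choice(200, 10, replace=False),
              rng.uniform(0.5, 1.0, 10) * rng.choice([-1.0, 1.0], 10))]
bulk, cohort, s_truth = simulate_bulk_survival(
    SurvSimConfig(n_samples=300, n_genes=200, causal_genes=causal, seed=2))
model = RiskScoreModel(seed=3).fit(cohort)
ev = evaluate_model(model.scores_, cohort)

calls = caller.calls_.set_index("cell_id")
planted = calls.index.isin(truth.malignant_cell_ids)
print(f"malignant calls: {calls['malignant'].sum()} of {len(calls)} cells")
print(f"sensitivity on planted cells: {calls.loc[planted, 'malignant'].mean():.3f}")
print(f"selected genes: {len(model.genes_)}, causal recovered: "
      f"{len(set(model.genes_) & set(s_truth.causal_betas))}/10")
print(f"risk-score HR {ev.hr:.2f} (95% CI {ev.hr_ci[0]:.2f}-{ev.hr_ci[1]:.2f}), "
      f"log-rank p {ev.logrank_p:.2e}")
print("time-dependent AUC:", {int(k): round(v, 3) for k, v in ev.auc.items()})
```

prints:

```
malignant calls: 133 of 600 cells
sensitivity on planted cells: 1.000
selected genes: 20, causal recovered: 9/10
risk-score HR 2.72 (95% CI 2.40-3.07), log-rank p 1.70e-49
time-dependent AUC: {24: 0.92, 48: 0.916, 72: 0.925, 96: 0.927}
```

133 of 600 cells are called malignant (126 were planted; the CNV caller
finds all of them plus a handful of borderline normals), the LASSO–Cox
chain keeps 20 genes of which 9 are truly causal, and the resulting risk
score separates the cohort strongly at every horizon.

A command-line interface mirrors the library:
`tiprog simulate | preprocess | cnv-call | score | metaprograms |
prognostic | drug-screen` (see `tiprog --help`).

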