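"""Two-criterion drug-sensitivity screen over a samples x drugs AUC table.

A drug passes when (1) its mean AUC is lower in the high-risk group than in
the low-risk group — expressed as ``log2fc_auc = log2(mean_low / mean_high)
> 0`` — and (2) the model's risk genes correlate negatively with its AUC
(aggregate r < -0.05).  Lower dose-response AUC means greater sensitivity,
so passing drugs are candidates for preferential efficacy in high-risk
patients.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr

from .containers import ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)

LOG2FC_THRESHOLD = 0.0
CORR_THRESHOLD = -0.05


@dataclass
class DrugScreenResult:
    drug_id: str
    source: str
    log2fc_auc: float
    gene_correlations: dict[str, float]
    aggregate_r: float
    passes: bool


def auc_log2fc(auc: pd.DataFrame, groups: pd.Series) -> pd.Series:
    """Per-drug log2(mean AUC in low risk / mean AUC in high risk).

    Positive values mean lower AUC (higher sensitivity) in the high-risk
    group.
    """
    shared = auc.index.intersection(groups.index)
    auc, groups = auc.loc[shared], groups.loc[shared]
    hi, lo = groups == "high", groups == "low"
    if not hi.any() or not lo.any():
        raise ValidationError("both risk groups must be nonempty")
    if (auc.to_numpy() <= 0).any():
        raise ValidationError("AUC values must be positive")
    return np.log2(auc[lo.to_numpy()].mean() / auc[hi.to_numpy()].mean()).rename("log2fc_auc")


def gene_auc_correlation(bulk: ExpressionMatrix, auc: pd.DataFrame,
                         risk_genes: list[str], method: str = "pearson",
                         agg: str = "mean") -> tuple[pd.DataFrame, pd.Series]:
    """Correlation of each risk gene's expression with each drug's AUC.

    Returns ``(genes x drugs correlation table, per-drug aggregate)`` where
    the aggregate is the mean (default), median, or minimum ("any") of the
    per-gene correlations.  Zero-variance vectors give r = 0 with a warning.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    if agg not in ("mean", "median", "any"):
        raise ValueError(f"unknown aggregation {agg!r}")
    shared = [s for s in bulk.obs_ids if s in set(auc.index)]
    if len(shared) < 3:
        raise ValidationError("need at least 3 samples shared between expression and AUC")
    missing = [g for g in risk_genes if g not in set(bulk.gene_ids)]
    if missing:
        raise ValidationError(f"risk genes absent from expression: {missing[:10]}")
    expr = bulk.select_obs(shared).to_frame().loc[risk_genes]
    auc = auc.loc[shared]

    corr = pd.DataFrame(index=risk_genes, columns=auc.columns, dtype=float)
    fn = pearsonr if method == "pearson" else spearmanr
    for g in risk_genes:
        x = expr.loc[g].to_numpy()
        for d in auc.columns:
            y = auc[d].to_numpy()
            if np.std(x) == 0 or np.std(y) == 0:
                warnings.warn(f"zero variance for ({g}, {d}); r set to 0")
                corr.loc[g, d] = 0.0
            else:
                corr.loc[g, d] = float(fn(x, y)[0])
    if agg == "mean":
        aggregate = corr.mean()
    elif agg == "median":
        aggregate = corr.median()
    else:  # "any": the most negative gene decides
        aggregate = corr.min()
    return corr, aggregate.rename("aggregate_r")


def screen_drugs(auc: pd.DataFrame, groups: pd.Series, bulk: ExpressionMatrix,
                 risk_genes: list[str], *, source: str = "synthetic",
                 method: str = "pearson", agg: str = "mean",
                 log2fc_threshold: float = LOG2FC_THRESHOLD,
                 corr_threshold: float = CORR_THRESHOLD) -> list[DrugScreenResult]:
    """Apply both criteria to every drug; results sorted by log2fc descending.

    passes == (log2fc_auc > 0) and (aggregate_r < -0.05).
    """
    shared = [s for s in bulk.obs_ids if s in set(auc.index) and s in set(groups.index)]
    if not shared:
        raise ValidationError("no samples shared across AUC, groups and expression")
    fc = auc_log2fc(auc.loc[shared], groups.loc[shared])
    corr, aggregate = gene_auc_correlation(bulk, auc, risk_genes, method, agg)
    results = [
        DrugScreenResult(
            drug_id=d, source=source,
            log2fc_auc=float(fc[d]),
            gene_correlations=corr[d].to_dict(),
            aggregate_r=float(aggregate[d]),
            passes=bool(fc[d] > log2fc_threshold and aggregate[d] < corr_threshold),
        )
        for d in auc.columns
    ]
    return sorted(results, key=lambda r: -r.log2fc_auc)


def screen_to_frame(results: list[DrugScreenResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "drug_id": r.drug_id, "source": r.source, "log2fc_auc": r.log2fc_auc,
        "aggregate_r": r.aggregate_r, "passes": r.passes,
    } for r in results])
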