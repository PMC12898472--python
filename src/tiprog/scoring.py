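"""Module scoring with binned expression controls, metaprogram assignment,
and cluster-level patient-specificity classification.

The module score of a cell for a gene set is the mean expression of the
set's genes minus the mean expression of a seeded control pool drawn, for
each signature gene, from the same average-expression bin — the
binned-control scoring scheme popularized by Seurat's AddModuleScore.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .containers import ExpressionMatrix, GeneSetCollection, ValidationError

logger = logging.getLogger(__name__)


class ModuleScorer(BaseEstimator):
    """Binned-control gene-set scorer (transform-shaped).

    Parameters
    ----------
    n_bins : int
        Number of equal-frequency average-expression bins.
    n_ctrl : int
        Control genes drawn per signature gene (from its bin, without
        replacement up to bin size).
    seed : int
        Seed for the control draws; fixes the scores completely.

    After :meth:`fit`, :meth:`transform` returns a cells x signatures score
    table.  ``control_genes_`` records the control pool per signature.
    """

    def __init__(self, n_bins: int = 25, n_ctrl: int = 100, seed: int = 0):
        self.n_bins = n_bins
        self.n_ctrl = n_ctrl
        self.seed = seed

    def fit(self, mat: ExpressionMatrix, sets: GeneSetCollection) -> "ModuleScorer":
        """Bin genes by average expression and draw seeded control pools."""
        if mat.layer != "lognorm":
            raise ValidationError("module scoring expects a lognorm-layer matrix")
        # bin assignment must not depend on gene row order: work on a
        # gene_id-sorted view
        order = sorted(range(mat.n_genes), key=lambda i: mat.gene_ids[i])
        gene_ids = [mat.gene_ids[i] for i in order]
        avg = mat.values[order, :].mean(axis=1)
        ranks = pd.Series(avg, index=gene_ids).rank(method="first")
        n_bins = min(self.n_bins, mat.n_genes)
        bins = pd.qcut(ranks, q=n_bins, labels=False)
        bin_members = {b: sorted(bins.index[bins == b]) for b in range(n_bins)}

        rng = np.random.default_rng(self.seed)
        matched: dict[str, list[str]] = {}
        controls: dict[str, list[str]] = {}
        present = set(gene_ids)
        for name in sorted(sets):
            genes = [g for g in sets[name] if g in present]
            if not genes:
                raise ValidationError(f"gene set {name!r} shares no genes with the matrix")
            dropped = len(sets[name]) - len(genes)
            if dropped:
                logger.info("set %s: dropped %d genes absent from the matrix", name, dropped)
            pool: set[str] = set()
            for g in sorted(genes):
                members = bin_members[int(bins[g])]
                k = min(self.n_ctrl, len(members))
                pool.update(rng.choice(members, size=k, replace=False))
            matched[name] = genes
            controls[name] = sorted(pool)
        self.signature_genes_ = matched
        self.control_genes_ = controls
        self.fitted_gene_ids_ = gene_ids
        return self

    def transform(self, mat: ExpressionMatrix) -> pd.DataFrame:
        """Score every fitted signature on ``mat`` (cells x signatures)."""
        if not hasattr(self, "signature_genes_"):
            raise ValidationError("ModuleScorer is not fitted")
        df = mat.to_frame()
        out = {}
        for name, genes in self.signature_genes_.items():
            sig_mean = df.loc[genes].mean(axis=0)
            ctrl_mean = df.loc[self.control_genes_[name]].mean(axis=0)
            out[name] = sig_mean - ctrl_mean
        return pd.DataFrame(out, index=mat.obs_ids)

    def fit_transform(self, mat: ExpressionMatrix, sets: GeneSetCollection) -> pd.DataFrame:
        return self.fit(mat, sets).transform(mat)


def score_modules(mat: ExpressionMatrix, sets: GeneSetCollection, n_bins: int = 25,
                  n_ctrl: int = 100, seed: int = 0) -> pd.DataFrame:
    """Functional wrapper over :class:`ModuleScorer`."""
    return ModuleScorer(n_bins=n_bins, n_ctrl=n_ctrl, seed=seed).fit_transform(mat, sets)


def assign_metaprogram(scores: pd.DataFrame) -> pd.Series:
    """Map each cell to its highest-scoring signature.

    Ties break by lexicographic signature name (columns are sorted before
    the argmax, and ``idxmax`` keeps the first maximum).
    """
    if scores.shape[1] < 1:
        raise ValidationError("no signatures scored")
    ordered = scores[sorted(scores.columns)]
    return ordered.idxmax(axis=1).rename("metaprogram")


def classify_cluster_specificity(meta: pd.DataFrame, threshold: float = 0.90) -> pd.DataFrame:
    """Classify clusters as patient-specific vs patient-shared.

    A cluster is patient-specific when its maximum single-patient cell
    fraction is >= ``threshold`` (inclusive).  Returns one row per cluster
    with columns cluster_label, n_cells, max_patient, max_patient_fraction,
    classification.
    """
    if meta["cluster_label"].isna().any() or meta["patient_id"].isna().any():
        raise ValidationError("every cell needs cluster_label and patient_id")
    rows = []
    for cluster, grp in meta.groupby("cluster_label"):
        if len(grp) == 0:
            warnings.warn(f"empty cluster {cluster!r} excluded")
            continue
        frac = grp["patient_id"].value_counts(normalize=True)
        rows.append({
            "cluster_label": cluster,
            "n_cells": len(grp),
            "max_patient": frac.idxmax(),
            "max_patient_fraction": float(frac.max()),
            "classification": ("patient_specific" if frac.max() >= threshold
                               else "patient_shared"),
        })
    return pd.DataFrame(rows)


def malignant_fraction_per_cluster(calls: pd.DataFrame, meta: pd.DataFrame) -> pd.Series:
    """Fraction of malignant cells per cluster.

    ``calls`` must cover every cell appearing in ``meta``.
    """
    call_map = calls.set_index("cell_id")["malignant"]
    missing = set(meta["cell_id"]) - set(call_map.index)
    if missing:
        raise ValidationError(f"cells without malignancy calls: {sorted(missing)[:10]}")
    labelled = meta.assign(malignant=call_map.loc[meta["cell_id"]].to_numpy())
    return labelled.groupby("cluster_label")["malignant"].mean().rename("malignant_fraction")
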