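"""Copy-number inference from expression and malignant-cell classification.

Per-cell CNV profiles are built from log-normalized expression by (1)
dropping uninformative genes, (2) gene-wise z-scoring clipped to [-3, 3],
(3) chromosome-ordered sliding-window averaging with per-cell centering,
and (4) subtracting the mean profile of non-epithelial reference cells.
Each cell is then summarized by two statistics:

* ``MS`` — the mean square of its CNV profile (signal strength), and
* ``CORR`` — the Pearson correlation of its profile with the average
  profile of the cells in the top 5% by MS.

A cell is called malignant when ``MS > 0.02`` or ``CORR > 0.2``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .containers import ExpressionMatrix, ValidationError, validate_gene_annotation

logger = logging.getLogger(__name__)

LOG2E_FACTOR = 1.0 / np.log(2.0)  # natural-log expression -> log2 scale


@dataclass
class CnvProfileMatrix:
    """Cells x genes smoothed, centered, reference-adjusted CNV estimates.

    Gene order is nondecreasing in (chromosome, start) and windows never
    span a chromosome boundary.
    """

    cell_ids: list[str]
    gene_ids: list[str]
    chromosomes: np.ndarray
    values: np.ndarray  # cells x genes
    window_size: int = 100

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.gene_ids)


def cnv_gene_filter(mat: ExpressionMatrix, min_cells: int = 10,
                    min_mean_log2: float = 0.1) -> ExpressionMatrix:
    """Drop genes expressed in fewer than ``min_cells`` cells or whose mean
    log2-scale expression is below ``min_mean_log2``; survivor order kept."""
    if mat.layer != "lognorm":
        raise ValidationError("cnv_gene_filter expects a lognorm-layer matrix")
    n_cells_expr = (mat.values > 0).sum(axis=1)
    mean_log2 = mat.values.mean(axis=1) * LOG2E_FACTOR
    keep = (n_cells_expr >= min_cells) & (mean_log2 >= min_mean_log2)
    if not keep.any():
        raise ValidationError("no genes survive the CNV informativeness filter")
    return mat.subset_genes(keep)


def zscore_clamp(mat: ExpressionMatrix, clip: float = 3.0) -> ExpressionMatrix:
    """Gene-wise z-score (sample sd) clipped to [-clip, clip].

    Zero-variance genes carry no relative signal and are dropped with a
    warning.
    """
    sd = mat.values.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance genes before z-scoring")
        mat = mat.subset_genes(keep)
        sd = sd[keep]
    z = (mat.values - mat.values.mean(axis=1, keepdims=True)) / sd[:, None]
    return mat.with_values(np.clip(z, -clip, clip), "zscore")


def _window_bounds(n: int, w: int) -> tuple[np.ndarray, np.ndarray]:
    """Half-open [lo, hi) window bounds of up to ``w`` genes centered on each
    of ``n`` positions, truncated at the block edges."""
    i = np.arange(n)
    left, right = (w - 1) // 2, w // 2
    return np.maximum(i - left, 0), np.minimum(i + right + 1, n)


def smooth_windows(z: ExpressionMatrix, ann: pd.DataFrame, w: int = 100,
                   centering: str = "median") -> CnvProfileMatrix:
    """Chromosome-ordered sliding-window mean of z-scores, then per-cell
    centering of the smoothed profile.

    Genes are sorted by (chromosome, start); each gene's smoothed value is
    the mean of z over up to ``w`` genes centered on it, never crossing a
    chromosome boundary.  ``centering`` subtracts each cell's median (or
    mean) smoothed value; ``none`` skips it.
    """
    if centering not in ("median", "mean", "none"):
        raise ValueError(f"unknown centering {centering!r}")
    ann = validate_gene_annotation(ann).set_index("gene_id")
    missing = [g for g in z.gene_ids if g not in ann.index]
    if missing:
        raise ValidationError(f"genes without annotation: {missing[:10]}")
    sub = ann.loc[z.gene_ids]
    order = np.lexsort((sub["start"].to_numpy(), sub["chromosome"].to_numpy()))
    gene_ids = [z.gene_ids[i] for i in order]
    chroms = sub["chromosome"].to_numpy()[order]
    vals = z.values[order, :].T  # cells x genes

    smoothed = np.empty_like(vals)
    col = 0
    for chrom in pd.unique(chroms):
        block = vals[:, chroms == chrom]
        n = block.shape[1]
        lo, hi = _window_bounds(n, w)
        csum = np.concatenate([np.zeros((block.shape[0], 1)), np.cumsum(block, axis=1)], axis=1)
        smoothed[:, col:col + n] = (csum[:, hi] - csum[:, lo]) / (hi - lo)
        col += n

    if centering == "median":
        smoothed -= np.median(smoothed, axis=1, keepdims=True)
    elif centering == "mean":
        smoothed -= smoothed.mean(axis=1, keepdims=True)
    return CnvProfileMatrix(list(z.obs_ids), gene_ids, chroms, smoothed, w)


def reference_adjust(profile: CnvProfileMatrix, reference_cells: set[str]) -> CnvProfileMatrix:
    """Subtract, per gene, the mean smoothed value over reference cells."""
    if not reference_cells:
        raise ValidationError("reference cell set is empty")
    pos = {c: i for i, c in enumerate(profile.cell_ids)}
    missing = [c for c in reference_cells if c not in pos]
    if missing:
        raise ValidationError(f"reference cells not in profile: {sorted(missing)[:10]}")
    ref_idx = [pos[c] for c in sorted(reference_cells)]
    ref_mean = profile.values[ref_idx, :].mean(axis=0)
    return CnvProfileMatrix(profile.cell_ids, profile.gene_ids, profile.chromosomes,
                            profile.values - ref_mean, profile.window_size)


def compute_ms(profile: CnvProfileMatrix) -> pd.Series:
    """Per-cell CNV signal strength: mean over genes of the squared profile."""
    return pd.Series(np.mean(profile.values ** 2, axis=1), index=profile.cell_ids, name="MS")


def compute_corr(profile: CnvProfileMatrix, ms: pd.Series,
                 top_fraction: float = 0.05) -> pd.Series:
    """Pearson correlation of each cell's profile with the mean profile of
    the top-``top_fraction`` cells by MS.

    The top set holds ``max(1, ceil(top_fraction * n_cells))`` cells; MS
    ties are broken by cell ID.  Zero-variance profiles get CORR = 0 with a
    warning.
    """
    n = len(profile.cell_ids)
    if n < 2:
        raise ValidationError("CORR needs at least 2 cells")
    k = max(1, int(np.ceil(top_fraction * n)))
    order = sorted(range(n), key=lambda i: (-ms.iloc[i], profile.cell_ids[i]))
    top_mean = profile.values[order[:k], :].mean(axis=0)

    tm = top_mean - top_mean.mean()
    tm_norm = np.sqrt((tm ** 2).sum())
    x = profile.values - profile.values.mean(axis=1, keepdims=True)
    x_norm = np.sqrt((x ** 2).sum(axis=1))
    corr = np.zeros(n)
    ok = (x_norm > 0) & (tm_norm > 0)
    if not ok.all():
        warnings.warn(f"{int((~ok).sum())} zero-variance profiles; CORR set to 0")
    if tm_norm > 0:
        corr[ok] = (x[ok] @ tm) / (x_norm[ok] * tm_norm)
    return pd.Series(np.clip(corr, -1.0, 1.0), index=profile.cell_ids, name="CORR")


def classify_malignant(ms: pd.Series, corr: pd.Series, ms_threshold: float = 0.02,
                       corr_threshold: float = 0.2) -> pd.Series:
    """Malignant iff MS strictly exceeds ``ms_threshold`` or CORR strictly
    exceeds ``corr_threshold``."""
    return ((ms > ms_threshold) | (corr > corr_threshold)).rename("malignant")


class CnvCaller(BaseEstimator):
    """Expression-based CNV profiling and malignant-cell classification.

    Parameters
    ----------
    window : int
        Sliding-window width in genes.
    min_cells, min_mean_log2 : filtering thresholds for informative genes.
    ms_threshold, corr_threshold, top_fraction : classification parameters.
    centering : {"median", "mean", "none"}
        Per-cell centering of the smoothed profile.
    reference_stage : {"after_smoothing", "off"}
        Where the reference subtraction is applied.
    stats_on : {"adjusted", "unadjusted"}
        Whether MS/CORR are computed on the reference-adjusted profile
        (default) or before the subtraction.

    Attributes
    ----------
    profile_ : CnvProfileMatrix
        Final per-cell CNV profile (reference-adjusted when enabled).
    calls_ : DataFrame with columns cell_id, MS, CORR, malignant.
    malignant_ids_ : list of cell IDs called malignant.
    """

    def __init__(self, window: int = 100, min_cells: int = 10, min_mean_log2: float = 0.1,
                 ms_threshold: float = 0.02, corr_threshold: float = 0.2,
                 top_fraction: float = 0.05, centering: str = "median",
                 reference_stage: str = "after_smoothing", stats_on: str = "adjusted"):
        self.window = window
        self.min_cells = min_cells
        self.min_mean_log2 = min_mean_log2
        self.ms_threshold = ms_threshold
        self.corr_threshold = corr_threshold
        self.top_fraction = top_fraction
        self.centering = centering
        self.reference_stage = reference_stage
        self.stats_on = stats_on

    def fit(self, mat: ExpressionMatrix, meta: pd.DataFrame, ann: pd.DataFrame) -> "CnvCaller":
        """Run the full pipeline on a lognorm matrix with cell metadata
        (compartment column decides query vs reference) and gene annotation."""
        query = meta.loc[meta["compartment"] == "epithelial", "cell_id"]
        reference = meta.loc[meta["compartment"] != "epithelial", "cell_id"]
        if query.empty or reference.empty:
            raise ValidationError("need both epithelial query cells and "
                                  "non-epithelial reference cells")
        filtered = cnv_gene_filter(mat, self.min_cells, self.min_mean_log2)
        z = zscore_clamp(filtered)
        smoothed = smooth_windows(z, ann, self.window, self.centering)
        if self.reference_stage == "after_smoothing":
            adjusted = reference_adjust(smoothed, set(reference))
        elif self.reference_stage == "off":
            adjusted = smoothed
        else:
            raise ValueError(f"unknown reference_stage {self.reference_stage!r}")
        stats_profile = adjusted if self.stats_on == "adjusted" else smoothed

        ms = compute_ms(stats_profile)
        corr = compute_corr(stats_profile, ms, self.top_fraction)
        malignant = classify_malignant(ms, corr, self.ms_threshold, self.corr_threshold)
        query_set = set(query)
        calls = pd.DataFrame({"cell_id": stats_profile.cell_ids, "MS": ms.values,
                              "CORR": corr.values, "malignant": malignant.values,
                              "is_query": [c in query_set for c in stats_profile.cell_ids]})
        self.profile_ = adjusted
        self.calls_ = calls
        self.malignant_ids_ = calls.loc[calls["malignant"] & calls["is_query"],
                                        "cell_id"].tolist()
        return self

    def predict(self, cell_ids: list[str] | None = None) -> pd.Series:
        """Malignant call per cell (all profiled cells by default)."""
        if not hasattr(self, "calls_"):
            raise ValidationError("CnvCaller is not fitted")
        calls = self.calls_.set_index("cell_id")["malignant"]
        return calls if cell_ids is None else calls.loc[list(cell_ids)]

    def summary(self) -> dict:
        return {
            "window": self.window, "ms_threshold": self.ms_threshold,
            "corr_threshold": self.corr_threshold, "top_fraction": self.top_fraction,
            "centering": self.centering, "reference_stage": self.reference_stage,
            "stats_on": self.stats_on,
            "n_cells": len(self.calls_), "n_malignant": int(self.calls_["malignant"].sum()),
        }


def run_cnv_pipeline(mat: ExpressionMatrix, meta: pd.DataFrame, ann: pd.DataFrame,
                     **params) -> tuple[pd.DataFrame, CnvProfileMatrix]:
    """Functional wrapper: returns ``(calls table, CNV profile)``."""
    caller = CnvCaller(**params).fit(mat, meta, ann)
    return caller.calls_, caller.profile_
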