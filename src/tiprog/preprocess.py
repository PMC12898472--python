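"""Quality control, normalization and highly-variable-gene selection.

Mirrors the standard droplet scRNA-seq preprocessing chain: drop low-quality
cells (few detected genes, high mitochondrial content), drop near-absent
genes, library-size normalize to a fixed scale with a log1p transform, and
rank genes by a variance-stabilized dispersion statistic.
"""

from __future__ import annotations

import logging

import numpy as np

from .containers import ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)


class EmptyOutputError(ValidationError):
    """QC removed every cell or gene."""


def qc_filter(mat: ExpressionMatrix, *, min_genes: int = 200, max_mito: float = 0.20,
              min_cells: int = 3, mito_prefix: str = "MT-") -> ExpressionMatrix:
    """Remove low-quality cells, then genes expressed in too few cells.

    A cell is kept when it has at least ``min_genes`` detected (nonzero)
    genes and a mitochondrial count fraction of at most ``max_mito``;
    mitochondrial genes are identified by ID prefix.  Among the surviving
    cells, genes detected in fewer than ``min_cells`` cells are removed.
    Row/column order of survivors is preserved.
    """
    if mat.layer != "counts":
        raise ValidationError("qc_filter requires a counts-layer matrix")
    detected = (mat.values > 0).sum(axis=0)
    is_mito = np.array([g.startswith(mito_prefix) for g in mat.gene_ids])
    totals = mat.values.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mat.values[is_mito, :].sum(axis=0) / totals, 0.0)
    keep_cells = (detected >= min_genes) & (mito_frac <= max_mito)
    if not keep_cells.any():
        raise EmptyOutputError("QC removed all cells")
    out = mat.subset_obs(keep_cells)
    gene_cells = (out.values > 0).sum(axis=1)
    keep_genes = gene_cells >= min_cells
    if not keep_genes.any():
        raise EmptyOutputError("QC removed all genes")
    n_cells_dropped = int((~keep_cells).sum())
    n_genes_dropped = int((~keep_genes).sum())
    if n_cells_dropped or n_genes_dropped:
        logger.info("QC removed %d cells and %d genes", n_cells_dropped, n_genes_dropped)
    return out.subset_genes(keep_genes)


def log_normalize(mat: ExpressionMatrix, scale: float = 10_000.0) -> ExpressionMatrix:
    """Library-size normalize counts to ``scale`` per cell and apply ln(1+x).

    value := ln(1 + scale * x / colsum), the LogNormalize convention with
    the natural logarithm.
    """
    if mat.layer != "counts":
        raise ValidationError("log_normalize requires a counts-layer matrix")
    colsums = mat.values.sum(axis=0)
    zero = np.flatnonzero(colsums == 0)
    if zero.size:
        names = [mat.obs_ids[i] for i in zero[:5]]
        raise ValidationError(f"cells with zero total counts: {names}")
    values = np.log1p(scale * mat.values / colsums)
    return mat.with_values(values, "lognorm")


def hvg_statistic(mat: ExpressionMatrix, fit_degree: int = 2) -> np.ndarray:
    """Variance-stabilized dispersion per gene.

    Per-gene log10 variance is regressed on log10 mean with a polynomial of
    ``fit_degree``; the statistic is the residual (observed minus expected
    log-variance).  Genes with zero variance get -inf and rank last.
    """
    mean = mat.values.mean(axis=1)
    var = mat.values.var(axis=1, ddof=1)
    stat = np.full(mat.n_genes, -np.inf)
    ok = (var > 0) & (mean > 0)
    if ok.sum() > fit_degree:
        lx, ly = np.log10(mean[ok]), np.log10(var[ok])
        coef = np.polyfit(lx, ly, deg=fit_degree)
        stat[ok] = ly - np.polyval(coef, lx)
    elif ok.any():  # too few genes to fit a trend; fall back to raw variance
        stat[ok] = np.log10(var[ok])
    return stat


def select_hvg(mat: ExpressionMatrix, n: int, fit_degree: int = 2) -> list[str]:
    """Top ``n`` highly variable genes, tie-broken by gene ID."""
    if n <= 0:
        raise ValueError("n must be positive")
    if n > mat.n_genes:
        raise ValueError(f"n={n} exceeds the {mat.n_genes} available genes")
    if mat.layer != "lognorm":
        raise ValidationError("select_hvg expects a lognorm-layer matrix")
    stat = hvg_statistic(mat, fit_degree=fit_degree)
    order = sorted(range(mat.n_genes), key=lambda i: (-stat[i], mat.gene_ids[i]))
    return [mat.gene_ids[i] for i in order[:n]]
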