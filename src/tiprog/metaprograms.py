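"""Per-sample multi-rank NMF on malignant cells and consensus metaprograms.

Each sample's malignant-cell expression (restricted to per-sample highly
variable genes) is factorized as V ~ W.H for every rank in ``k_range``;
every factor yields a gene-weight program and a signature (the smallest
prefix of weight-sorted genes explaining a fixed share of total weight).
Programs from all samples and ranks are then clustered by cosine
similarity (average linkage) into ``n_mp`` consensus metaprograms; a gene
enters a consensus signature when it appears in at least ``min_confidence``
of the member programs' signatures.

The factorization is a multiplicative-update Frobenius NMF with a
deterministic NNDSVD-style initialization, so results are reproducible.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator

from .containers import ExpressionMatrix, GeneSetCollection, ValidationError
from .preprocess import select_hvg

logger = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass
class NmfProgram:
    """One NMF factor: a nonnegative gene-weight vector plus its signature."""

    sample_id: str
    rank: int
    factor: int
    weights: pd.Series  # indexed by gene_id, >= 0
    signature: list[str] = field(default_factory=list)

    @property
    def program_id(self) -> str:
        return f"{self.sample_id}.k{self.rank}.{self.factor}"


@dataclass
class Metaprogram:
    name: str
    member_programs: list[str]
    confidence: pd.Series  # gene -> fraction of member signatures containing it
    signature: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# NMF solver
# ---------------------------------------------------------------------------

def _nndsvd_init(V: np.ndarray, k: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic NNDSVD initialization; zero entries filled with the
    matrix mean (the 'a' variant) so multiplicative updates cannot stall."""
    try:
        U, S, Vt = np.linalg.svd(V, full_matrices=False)
    except np.linalg.LinAlgError:  # pragma: no cover - degenerate input
        scale = np.sqrt(V.mean() / k) if V.mean() > 0 else 1.0
        return (scale * rng.random((V.shape[0], k)),
                scale * rng.random((k, V.shape[1])))
    W = np.zeros((V.shape[0], k))
    H = np.zeros((k, V.shape[1]))
    W[:, 0] = np.sqrt(S[0]) * np.abs(U[:, 0])
    H[0, :] = np.sqrt(S[0]) * np.abs(Vt[0, :])
    for j in range(1, min(k, len(S))):
        u, v = U[:, j], Vt[j, :]
        up, un = np.maximum(u, 0), np.maximum(-u, 0)
        vp, vn = np.maximum(v, 0), np.maximum(-v, 0)
        n_up, n_un = np.linalg.norm(up), np.linalg.norm(un)
        n_vp, n_vn = np.linalg.norm(vp), np.linalg.norm(vn)
        if n_up * n_vp >= n_un * n_vn:
            sigma = n_up * n_vp
            x, y = up / max(n_up, _EPS), vp / max(n_vp, _EPS)
        else:
            sigma = n_un * n_vn
            x, y = un / max(n_un, _EPS), vn / max(n_vn, _EPS)
        W[:, j] = np.sqrt(S[j] * sigma) * x
        H[j, :] = np.sqrt(S[j] * sigma) * y
    avg = V.mean()
    W[W <= 0] = avg
    H[H <= 0] = avg
    return W, H


def nmf_factorize(V: np.ndarray, k: int, *, max_iter: int = 500, tol: float = 1e-5,
                  seed: int = 0) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Frobenius NMF by multiplicative updates.

    Returns ``(W, H, loss_curve)``; the loss curve is the Frobenius norm of
    the residual after each iteration and is non-increasing.
    """
    V = np.asarray(V, float)
    if np.any(V < 0):
        raise ValidationError("NMF input must be nonnegative")
    rng = np.random.default_rng(seed)
    W, H = _nndsvd_init(V, k, rng)
    losses = [float(np.linalg.norm(V - W @ H))]
    for _ in range(max_iter):
        H *= (W.T @ V) / (W.T @ W @ H + _EPS)
        W *= (V @ H.T) / (W @ (H @ H.T) + _EPS)
        loss = float(np.linalg.norm(V - W @ H))
        losses.append(loss)
        if losses[-2] - loss <= tol * max(losses[0], _EPS):
            break
    return W, H, losses


def extract_signature(weights: pd.Series, weight_explained: float = 0.8,
                      max_genes: int = 50) -> list[str]:
    """Smallest prefix of descending-weight genes whose cumulative weight
    reaches ``weight_explained`` of the total, capped at ``max_genes``."""
    total = float(weights.sum())
    if total <= 0:
        raise ValidationError("all-zero factor has no signature")
    # weight descending, gene id ascending on ties (stable sort after id sort)
    ordered = weights.sort_index().sort_values(ascending=False, kind="mergesort")
    cum = ordered.cumsum() / total
    n = int(np.searchsorted(cum.to_numpy(), weight_explained) + 1)
    n = min(n, max_genes, int((ordered > 0).sum()))
    return list(ordered.index[:n])


def run_nmf_multirank(mats_by_sample: dict[str, ExpressionMatrix],
                      k_range: tuple[int, ...] = (4, 5, 6, 7, 8, 9),
                      nfeatures: int = 1000, *, scale: bool = True,
                      weight_explained: float = 0.8,
                      max_genes: int = 50, max_iter: int = 500, tol: float = 1e-5,
                      seed: int = 0) -> list[NmfProgram]:
    """Multi-rank NMF over per-sample malignant-cell matrices.

    Each sample is restricted to its own top ``nfeatures`` variable genes.
    With ``scale`` (the field convention) each gene is z-scored across the
    sample's cells and negative values are truncated at zero, so factors
    capture above-average co-expression rather than baseline expression
    level.  Samples with fewer cells than ``max(k_range)`` are skipped with
    a warning.
    """
    programs: list[NmfProgram] = []
    k_max = max(k_range)
    for sample in sorted(mats_by_sample):
        mat = mats_by_sample[sample]
        if mat.n_obs < k_max:
            warnings.warn(f"sample {sample!r} has {mat.n_obs} cells < k_max={k_max}; skipped")
            continue
        hvg = select_hvg(mat, min(nfeatures, mat.n_genes))
        sub = mat.subset_genes([mat.gene_ids.index(g) for g in hvg])
        V = sub.values
        if scale:
            sd = V.std(axis=1, ddof=0)
            sd[sd == 0] = 1.0
            V = np.maximum((V - V.mean(axis=1, keepdims=True)) / sd[:, None], 0.0)
        for k in k_range:
            W, _, _ = nmf_factorize(V, k, max_iter=max_iter, tol=tol, seed=seed)
            for f in range(k):
                weights = pd.Series(W[:, f], index=sub.gene_ids)
                programs.append(NmfProgram(sample, k, f, weights,
                                           extract_signature(weights, weight_explained,
                                                             max_genes)))
    return programs


# ---------------------------------------------------------------------------
# consensus integration
# ---------------------------------------------------------------------------

def _weight_matrix(programs: list[NmfProgram],
                   restrict_to_signature: bool = True) -> tuple[np.ndarray, list[str]]:
    genes = sorted(set().union(*(p.weights.index for p in programs)))
    A = np.zeros((len(programs), len(genes)))
    pos = {g: i for i, g in enumerate(genes)}
    for r, p in enumerate(programs):
        keep = set(p.signature) if (restrict_to_signature and p.signature) else None
        for g, w in p.weights.items():
            if keep is None or g in keep:
                A[r, pos[g]] = w
    return A, genes


def cosine_similarity_matrix(programs: list[NmfProgram],
                             restrict_to_signature: bool = True) -> np.ndarray:
    """Pairwise cosine similarity of program weight vectors, aligned on the
    gene union (missing genes weigh 0).

    By default each program's weights are restricted to its signature genes
    first; the dense low-weight background every factor of a sample shares
    would otherwise dominate the similarity and cluster programs by sample
    rather than by shared gene content.
    """
    A, _ = _weight_matrix(programs, restrict_to_signature)
    norms = np.linalg.norm(A, axis=1)
    norms[norms == 0] = _EPS
    S = (A @ A.T) / np.outer(norms, norms)
    return np.clip(S, -1.0, 1.0)


def integrate_programs(programs: list[NmfProgram], n_mp: int = 8,
                       min_confidence: float = 0.3,
                       max_genes: int = 50) -> list[Metaprogram]:
    """Cluster programs into ``n_mp`` consensus metaprograms.

    Average-linkage hierarchical clustering on (1 - cosine similarity),
    tree cut at exactly ``n_mp`` clusters; singletons are allowed.  The
    consensus signature keeps genes present in at least ``min_confidence``
    of the member programs' signatures.
    """
    if len(programs) < n_mp:
        raise ValidationError(f"{len(programs)} programs < n_mp={n_mp}")
    S = cosine_similarity_matrix(programs)
    D = 1.0 - S
    np.fill_diagonal(D, 0.0)
    D = np.maximum((D + D.T) / 2.0, 0.0)
    Z = sch.linkage(squareform(D, checks=False), method="average")
    labels = sch.fcluster(Z, t=n_mp, criterion="maxclust")

    out: list[Metaprogram] = []
    clusters = sorted(set(labels), key=lambda c: (-np.sum(labels == c), c))
    for rank, c in enumerate(clusters, start=1):
        members = [programs[i] for i in np.flatnonzero(labels == c)]
        genes = sorted(set().union(*(set(m.signature) for m in members)))
        conf = pd.Series(
            [np.mean([g in set(m.signature) for m in members]) for g in genes],
            index=genes, dtype=float)
        keep = conf[conf >= min_confidence]
        # deterministic order: confidence desc, then gene id
        sig = sorted(keep.index, key=lambda g: (-keep[g], g))[:max_genes]
        out.append(Metaprogram(f"MP{rank}", [m.program_id for m in members], conf, sig))
    return out


def metaprograms_to_gene_sets(metaprograms: list[Metaprogram]) -> GeneSetCollection:
    return GeneSetCollection({mp.name: list(mp.signature) for mp in metaprograms},
                             {mp.name: f"consensus of {len(mp.member_programs)} programs"
                              for mp in metaprograms})


def correlate_metaprograms(scores: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between per-cell metaprogram scores.

    Unit diagonal; zero-variance score columns yield 0 off-diagonal entries
    with a warning.
    """
    if len(scores) < 3:
        raise ValidationError("need at least 3 scored cells")
    sd = scores.std(ddof=1)
    bad = sd[sd == 0].index.tolist()
    if bad:
        warnings.warn(f"zero-variance score columns: {bad}")
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(scores.to_numpy().T)
    C = np.nan_to_num(C, nan=0.0)
    np.fill_diagonal(C, 1.0)
    return pd.DataFrame(np.clip(C, -1, 1), index=scores.columns, columns=scores.columns)


class MetaprogramDiscovery(BaseEstimator):
    """End-to-end metaprogram discovery (decomposition-shaped estimator).

    ``fit`` consumes a mapping sample_id -> lognorm ExpressionMatrix of that
    sample's malignant cells and populates ``programs_``, ``metaprograms_``
    and ``similarity_``.
    """

    def __init__(self, k_range: tuple[int, ...] = (4, 5, 6, 7, 8, 9),
                 nfeatures: int = 1000, n_mp: int = 8, weight_explained: float = 0.8,
                 min_confidence: float = 0.3, max_signature_genes: int = 50,
                 max_iter: int = 500, tol: float = 1e-5, seed: int = 0):
        self.k_range = k_range
        self.nfeatures = nfeatures
        self.n_mp = n_mp
        self.weight_explained = weight_explained
        self.min_confidence = min_confidence
        self.max_signature_genes = max_signature_genes
        self.max_iter = max_iter
        self.tol = tol
        self.seed = seed

    def fit(self, mats_by_sample: dict[str, ExpressionMatrix]) -> "MetaprogramDiscovery":
        self.programs_ = run_nmf_multirank(
            mats_by_sample, tuple(self.k_range), self.nfeatures,
            weight_explained=self.weight_explained, max_genes=self.max_signature_genes,
            max_iter=self.max_iter, tol=self.tol, seed=self.seed)
        self.metaprograms_ = integrate_programs(self.programs_, self.n_mp,
                                                self.min_confidence,
                                                self.max_signature_genes)
        self.similarity_ = cosine_similarity_matrix(self.programs_)
        return self

    def gene_sets(self) -> GeneSetCollection:
        return metaprograms_to_gene_sets(self.metaprograms_)
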