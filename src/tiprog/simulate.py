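"""Synthetic single-cell, survival and drug-response data with planted truth.

Three generators back the test surface of the whole pipeline:

* :func:`simulate_scrna` — negative-binomial counts with patient structure,
  contiguous copy-number segments planted in a malignant epithelial subset,
  and co-expressed gene programs planted in subsets of the malignant cells.
* :func:`simulate_bulk_survival` — a bulk cohort whose hazard is log-linear
  in a known causal gene subset, with independent uniform censoring.
* :func:`simulate_drug_response` — a samples x drugs AUC table in which a
  chosen subset of drugs is deliberately anticorrelated with a risk score.

Every generator is deterministic for a fixed seed, and each returns a
truth container that is index-consistent with the emitted matrices.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.optimize

from .containers import ExpressionMatrix, SurvivalCohort, ValidationError


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class CnvSegment:
    """A contiguous copy-number segment: ``gene_span`` is a half-open index
    range within the chromosome's gene order; ``log2_fold`` in [-1, 1]."""

    chromosome: str
    gene_span: tuple[int, int]
    log2_fold: float


@dataclass
class ProgramSpec:
    """A planted co-expression program: ``gene_set_size`` genes whose
    negative-binomial means are multiplied by (1 + ``effect_size``) in an
    ``active_cell_fraction`` of the malignant cells."""

    gene_set_size: int
    active_cell_fraction: float
    effect_size: float


@dataclass
class ScSimConfig:
    n_patients: int = 3
    cells_per_patient: int = 200
    n_genes: int = 12000
    n_chromosomes: int = 16
    malignant_fraction: float = 0.3
    reference_fraction: float = 0.3
    cnv_segments: list[CnvSegment] = field(default_factory=list)
    program_specs: list[ProgramSpec] = field(default_factory=list)
    nb_dispersion: float = 2.0
    # residual per-gene patient effect (log-normal sd); kept small because the
    # emitted matrix emulates batch-corrected expression
    patient_effect_sigma: float = 0.05
    base_mean_log_mu: float = np.log(0.5)
    base_mean_log_sigma: float = 1.0
    n_mito_genes: int = 10
    mito_mean: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        for frac, what in [(self.malignant_fraction, "malignant_fraction"),
                           (self.reference_fraction, "reference_fraction")]:
            if not 0 <= frac <= 1:
                raise ValidationError(f"{what} must lie in [0, 1]")
        for seg in self.cnv_segments:
            if not -1 <= seg.log2_fold <= 1:
                raise ValidationError("segment log2_fold must lie in [-1, 1]")
        for spec in self.program_specs:
            if not 0 <= spec.active_cell_fraction <= 1:
                raise ValidationError("active_cell_fraction must lie in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValidationError("nb_dispersion must be positive")


@dataclass
class SurvSimConfig:
    n_samples: int = 300
    n_genes: int = 200
    causal_genes: list[tuple[str, float]] = field(default_factory=list)
    baseline_hazard: float = 0.02  # events per month
    censor_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.censor_rate < 1:
            raise ValidationError("censor_rate must lie in [0, 1)")
        if self.baseline_hazard <= 0:
            raise ValidationError("baseline_hazard must be positive")
        for _, beta in self.causal_genes:
            if not np.isfinite(beta):
                raise ValidationError("causal betas must be finite")


@dataclass
class SimTruth:
    """Planted ground truth paired with a simulated dataset."""

    malignant_cell_ids: list[str] = field(default_factory=list)
    program_genes: dict[str, list[str]] = field(default_factory=dict)
    program_active_cells: dict[str, list[str]] = field(default_factory=dict)
    segment_genes: dict[str, list[str]] = field(default_factory=dict)
    causal_betas: dict[str, float] = field(default_factory=dict)
    sensitive_drugs: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# single-cell simulator
# ---------------------------------------------------------------------------

def _make_annotation(cfg: ScSimConfig) -> pd.DataFrame:
    genes = [f"MT-G{i}" if i < cfg.n_mito_genes else f"G{i:05d}"
             for i in range(cfg.n_genes)]
    per_chrom = int(np.ceil(cfg.n_genes / cfg.n_chromosomes))
    chroms, starts = [], []
    for i in range(cfg.n_genes):
        chroms.append(f"chr{i // per_chrom + 1}")
        starts.append((i % per_chrom) * 1000)
    return pd.DataFrame({"gene_id": genes, "chromosome": chroms, "start": starts})


def _segment_gene_indices(cfg: ScSimConfig, ann: pd.DataFrame) -> dict[int, np.ndarray]:
    """Resolve segments to global gene indices; reject overlaps and overruns."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    out: dict[int, np.ndarray] = {}
    chrom_idx = {c: np.flatnonzero(ann["chromosome"].to_numpy() == c)
                 for c in ann["chromosome"].unique()}
    for si, seg in enumerate(cfg.cnv_segments):
        if seg.chromosome not in chrom_idx:
            raise ValidationError(f"segment chromosome {seg.chromosome!r} not in annotation")
        lo, hi = seg.gene_span
        n_on_chrom = chrom_idx[seg.chromosome].size
        if not (0 <= lo < hi <= n_on_chrom):
            raise ValidationError(
                f"segment span {seg.gene_span} outside chromosome {seg.chromosome} "
                f"({n_on_chrom} genes)")
        for plo, phi in by_chrom.get(seg.chromosome, []):
            if lo < phi and plo < hi:
                raise ValidationError(f"overlapping segments on {seg.chromosome}")
        by_chrom.setdefault(seg.chromosome, []).append((lo, hi))
        out[si] = chrom_idx[seg.chromosome][lo:hi]
    return out


def simulate_scrna(cfg: ScSimConfig) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame, SimTruth]:
    """Simulate a patient-structured scRNA-seq count matrix.

    Returns ``(counts, cell_metadata, gene_annotation, truth)``.  Counts are
    negative binomial with log-normal per-gene base means; malignant
    epithelial cells have the means of planted segment genes multiplied by
    ``2**log2_fold``; program-active malignant cells have program gene means
    multiplied by ``1 + effect_size``.  Non-epithelial (immune/stromal)
    reference cells carry neither CNV nor programs.
    """
    rng = np.random.default_rng(cfg.seed)
    ann = _make_annotation(cfg)
    seg_idx = _segment_gene_indices(cfg, ann)
    genes = ann["gene_id"].tolist()

    base_mean = rng.lognormal(cfg.base_mean_log_mu, cfg.base_mean_log_sigma, cfg.n_genes)
    base_mean[:cfg.n_mito_genes] = cfg.mito_mean

    # cells: per patient, a reference (immune/stromal) block and an epithelial
    # block of which a malignant_fraction carries the planted segments
    rows = []
    for p in range(cfg.n_patients):
        patient = f"P{p + 1}"
        n_ref = int(round(cfg.reference_fraction * cfg.cells_per_patient))
        n_epi = cfg.cells_per_patient - n_ref
        n_mal = int(round(cfg.malignant_fraction * n_epi))
        for c in range(cfg.cells_per_patient):
            if c < n_ref:
                comp = "immune" if c % 2 == 0 else "stromal"
                mal = False
            else:
                comp = "epithelial"
                mal = (c - n_ref) < n_mal
            rows.append((f"{patient}_C{c:04d}", patient, comp, mal))
    meta = pd.DataFrame(rows, columns=["cell_id", "patient_id", "compartment", "_malignant"])
    n_cells = len(meta)
    malignant = meta["_malignant"].to_numpy()
    mal_ids = meta.loc[malignant, "cell_id"].tolist()

    # per-cell mean matrix: base means, patient-level scaling, planted effects
    patient_factor = {f"P{p + 1}": rng.lognormal(0.0, cfg.patient_effect_sigma, cfg.n_genes)
                      for p in range(cfg.n_patients)}
    mean = np.empty((cfg.n_genes, n_cells))
    for j, (patient, is_mal) in enumerate(zip(meta["patient_id"], malignant)):
        m = base_mean * patient_factor[patient]
        if is_mal:
            m = m.copy()
            for si, idx in seg_idx.items():
                m[idx] *= 2.0 ** cfg.cnv_segments[si].log2_fold
        mean[:, j] = m

    # planted programs: disjoint gene sets outside segments and mito genes,
    # drawn from the upper half of base expression (programs are built from
    # robustly expressed genes); active cell sets partition the malignant
    # cells so program states are mutually exclusive
    used = set(np.concatenate(list(seg_idx.values())) if seg_idx else [])
    used |= set(range(cfg.n_mito_genes))
    candidates = np.array(sorted(set(range(cfg.n_genes)) - used))
    high_expr = candidates[base_mean[candidates] >= np.median(base_mean[candidates])]
    free = high_expr
    truth = SimTruth(malignant_cell_ids=mal_ids,
                     segment_genes={str(si): [genes[i] for i in idx]
                                    for si, idx in seg_idx.items()})
    mal_pos = rng.permutation(np.flatnonzero(malignant))
    if sum(s.active_cell_fraction for s in cfg.program_specs) > 1.0 + 1e-9:
        raise ValidationError("program active_cell_fractions must sum to at most 1")
    next_cell = 0
    for pi, spec in enumerate(cfg.program_specs):
        if spec.gene_set_size > free.size:
            raise ValidationError("not enough free genes for the requested programs")
        pg = rng.choice(free, size=spec.gene_set_size, replace=False)
        free = np.array(sorted(set(free) - set(pg)))
        n_active = int(round(spec.active_cell_fraction * len(mal_pos)))
        active = mal_pos[next_cell:next_cell + n_active]
        next_cell += n_active
        mean[np.ix_(pg, active)] *= 1.0 + spec.effect_size
        name = f"program_{pi + 1}"
        truth.program_genes[name] = [genes[i] for i in np.sort(pg)]
        truth.program_active_cells[name] = meta["cell_id"].iloc[np.sort(active)].tolist()

    # NB(mean m, dispersion theta): var = m + m^2/theta
    theta = cfg.nb_dispersion
    counts = rng.negative_binomial(theta, theta / (theta + mean)).astype(float)

    mat = ExpressionMatrix(genes, meta["cell_id"].tolist(), counts, "counts")
    meta = meta.drop(columns="_malignant")
    meta["tissue"] = "tumor"
    meta["cluster_label"] = [
        f"{p}_{'mal' if cid in set(mal_ids) else comp}"
        for cid, p, comp in zip(meta["cell_id"], meta["patient_id"], meta["compartment"])
    ]
    return mat, meta, ann, truth


# ---------------------------------------------------------------------------
# bulk survival simulator
# ---------------------------------------------------------------------------

def simulate_bulk_survival(cfg: SurvSimConfig) -> tuple[ExpressionMatrix, SurvivalCohort, SimTruth]:
    """Simulate a bulk cohort with exponential survival, log-linear hazard.

    Expression is log-normal per gene; the hazard of sample *j* is
    ``baseline_hazard * exp(sum_i beta_i * z_ij)`` where *z* is the
    gene-standardized expression.  Censoring times are uniform on (0, a)
    with *a* calibrated so the realized censoring fraction is close to
    ``censor_rate``.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = [f"G{i:05d}" for i in range(cfg.n_genes)]
    gene_pos = {g: i for i, g in enumerate(genes)}
    for g, _ in cfg.causal_genes:
        if g not in gene_pos:
            raise ValidationError(f"causal gene {g!r} not among simulated genes")

    mu = rng.normal(2.0, 0.5, cfg.n_genes)
    expr = np.exp(mu[:, None] + rng.normal(0.0, 1.0, (cfg.n_genes, cfg.n_samples)))
    z = (expr - expr.mean(axis=1, keepdims=True)) / expr.std(axis=1, ddof=1, keepdims=True)

    lp = np.zeros(cfg.n_samples)
    for g, beta in cfg.causal_genes:
        lp += beta * z[gene_pos[g]]
    hazard = cfg.baseline_hazard * np.exp(lp)
    event_time = rng.exponential(1.0 / hazard)

    if cfg.censor_rate == 0:
        time, event = event_time, np.ones(cfg.n_samples, int)
    else:
        def censored_frac(a: float) -> float:
            # P(C < T) for C ~ U(0, a): E[min(T, a)] / a
            return float(np.mean(np.minimum(event_time, a)) / a) - cfg.censor_rate

        hi = float(event_time.max()) * 100
        a = scipy.optimize.brentq(censored_frac, 1e-9, hi)
        censor_time = rng.uniform(0.0, a, cfg.n_samples)
        event = (event_time <= censor_time).astype(int)
        time = np.minimum(event_time, censor_time)
    time = np.maximum(time, 1e-6)

    samples = [f"S{i:04d}" for i in range(cfg.n_samples)]
    mat = ExpressionMatrix(genes, samples, expr, "lognorm")
    tab = pd.DataFrame({"sample_id": samples, "time": time, "event": event})
    truth = SimTruth(causal_betas=dict(cfg.causal_genes))
    return mat, SurvivalCohort(mat, tab), truth


# ---------------------------------------------------------------------------
# drug-response simulator
# ---------------------------------------------------------------------------

def simulate_drug_response(risk_scores: pd.Series, n_drugs: int = 20, n_sensitive: int = 3,
                           effect: float = 0.2, noise_sd: float = 0.05,
                           seed: int = 0) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate a samples x drugs AUC table tied to a risk score.

    The first ``n_sensitive`` drugs (after a seeded shuffle of names) get
    ``AUC = a_d - effect * z(risk) + eps``; the rest ``AUC = a_d + eps``.
    AUC values are clipped at zero.  Lower AUC = more sensitive, so the
    planted drugs are more effective in high-risk samples.
    """
    if n_sensitive > n_drugs:
        raise ValidationError("n_sensitive cannot exceed n_drugs")
    rng = np.random.default_rng(seed)
    r = np.asarray(risk_scores, float)
    z = (r - r.mean()) / (r.std(ddof=1) if r.std(ddof=1) > 0 else 1.0)
    drugs = [f"drug_{d + 1:03d}" for d in range(n_drugs)]
    sensitive = [str(d) for d in rng.choice(drugs, size=n_sensitive, replace=False)]
    baseline = rng.uniform(0.8, 0.95, n_drugs)
    auc = np.empty((len(r), n_drugs))
    for d, name in enumerate(drugs):
        eps = rng.normal(0.0, noise_sd, len(r))
        auc[:, d] = baseline[d] + eps - (effect * z if name in sensitive else 0.0)
    auc = np.clip(auc, 0.0, None)
    table = pd.DataFrame(auc, index=list(risk_scores.index), columns=drugs)
    return table, SimTruth(sensitive_drugs=sorted(sensitive))
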