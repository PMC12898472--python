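import numpy as np
import pandas as pd
import pytest

from tiprog.containers import ExpressionMatrix
from tiprog.preprocess import log_normalize, qc_filter
from tiprog.simulate import (
    CnvSegment,
    ProgramSpec,
    ScSimConfig,
    SurvSimConfig,
    simulate_bulk_survival,
    simulate_scrna,
)


@pytest.fixture(scope="session")
def small_sc():
    """A small patient-structured count matrix with one planted program."""
    cfg = ScSimConfig(n_patients=2, cells_per_patient=60, n_genes=500,
                      n_chromosomes=4, malignant_fraction=0.4,
                      program_specs=[ProgramSpec(20, 0.5, 2.0)], seed=42)
    return simulate_scrna(cfg)


@pytest.fixture(scope="session")
def small_lognorm(small_sc):
    mat, meta, ann, truth = small_sc
    return log_normalize(qc_filter(mat, min_genes=50)), meta, ann, truth


@pytest.fixture(scope="session")
def cnv_sim():
    """CNV recovery conditions: 3 planted segments of 300 genes at |log2FC| 0.5."""
    cfg = ScSimConfig(
        cnv_segments=[CnvSegment("chr1", (50, 350), 0.5),
                      CnvSegment("chr3", (100, 400), -0.5),
                      CnvSegment("chr7", (0, 300), 0.5)],
        seed=7,
    )
    return simulate_scrna(cfg)


@pytest.fixture(scope="session")
def surv_cohort():
    """Bulk survival cohort with 10 causal genes, |beta| in [0.5, 1]."""
    rng = np.random.default_rng(1)
    idx = rng.choice(200, 10, replace=False)
    betas = rng.uniform(0.5, 1.0, 10) * rng.choice([-1.0, 1.0], 10)
    causal = [(f"G{i:05d}", float(b)) for i, b in zip(idx, betas)]
    cfg = SurvSimConfig(n_samples=300, n_genes=200, causal_genes=causal, seed=2)
    bulk, cohort, truth = simulate_bulk_survival(cfg)
    return bulk, cohort, truth


@pytest.fixture
def toy_matrix():
    """4 genes x 3 cells lognorm matrix with simple values."""
    vals = np.array([[1.0, 0.5, 0.0],
                     [0.2, 0.2, 0.2],
                     [0.0, 1.0, 2.0],
                     [3.0, 2.0, 1.0]])
    return ExpressionMatrix([f"g{i}" for i in range(4)], ["c0", "c1", "c2"],
                            vals, "lognorm")
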