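"""Readers and writers for the external formats the pipeline consumes.

Expression comes in as either a Matrix Market sparse triplet alongside
``genes.tsv``/``barcodes.tsv`` ID files (the CellRanger-style layout) or a
dense TSV with genes as rows.  Gene sets use GMT; metadata, annotation,
survival and drug tables are headered TSVs.
"""

from __future__ import annotations

import importlib.resources
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import (
    ExpressionMatrix,
    GeneSetCollection,
    SurvivalCohort,
    ValidationError,
    validate_cell_metadata,
    validate_gene_annotation,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_expression(path: str | Path, format: str = "dense_tsv", *,
                    genes_file: str | Path | None = None,
                    barcodes_file: str | Path | None = None,
                    layer: str = "counts") -> ExpressionMatrix:
    """Read an expression matrix.

    Parameters
    ----------
    path
        For ``dense_tsv``: a TSV with gene rows, observation columns and a
        header of observation IDs (first column = gene IDs).  For
        ``mtx_triplet``: the ``.mtx`` file; gene and barcode ID files default
        to ``genes.tsv``/``barcodes.tsv`` next to it.
    format : {"dense_tsv", "mtx_triplet"}
    layer
        Layer tag for the returned matrix (default ``counts``).
    """
    path = Path(path)
    if format == "dense_tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return ExpressionMatrix(list(df.index.astype(str)), list(df.columns.astype(str)),
                                df.to_numpy(float), layer)
    if format == "mtx_triplet":
        genes_file = Path(genes_file) if genes_file else path.parent / "genes.tsv"
        barcodes_file = Path(barcodes_file) if barcodes_file else path.parent / "barcodes.tsv"
        mat = scipy.io.mmread(path)
        values = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float)
        gene_ids = pd.read_csv(genes_file, sep="\t", header=None)[0].astype(str).tolist()
        obs_ids = pd.read_csv(barcodes_file, sep="\t", header=None)[0].astype(str).tolist()
        if values.shape != (len(gene_ids), len(obs_ids)):
            raise ValidationError(
                f"matrix dimensions {values.shape} do not match {len(gene_ids)} genes "
                f"x {len(obs_ids)} barcodes"
            )
        return ExpressionMatrix(gene_ids, obs_ids, values, layer)
    raise ValueError(f"unknown expression format {format!r}")


def write_expression(mat: ExpressionMatrix, path: str | Path, format: str = "dense_tsv") -> None:
    """Write an expression matrix in one of the formats ``read_expression`` reads."""
    path = Path(path)
    if format == "dense_tsv":
        mat.to_frame().to_csv(path, sep="\t")
    elif format == "mtx_triplet":
        path.parent.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(mat.values))
        pd.Series(mat.gene_ids).to_csv(path.parent / "genes.tsv", sep="\t",
                                       header=False, index=False)
        pd.Series(mat.obs_ids).to_csv(path.parent / "barcodes.tsv", sep="\t",
                                      header=False, index=False)
    else:
        raise ValueError(f"unknown expression format {format!r}")


# ---------------------------------------------------------------------------
# tabular inputs
# ---------------------------------------------------------------------------

def read_cell_metadata(path: str | Path, mat: ExpressionMatrix | None = None) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "patient_id": str})
    return validate_cell_metadata(meta, mat)


def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    """Read a BED-like gene annotation TSV with columns gene_id, chromosome, start."""
    ann = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chromosome": str})
    return validate_gene_annotation(ann)


def read_survival_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return df


def read_survival_cohort(expression_path: str | Path, survival_path: str | Path,
                         layer: str = "lognorm") -> SurvivalCohort:
    """Read bulk expression + survival table and align samples.

    Samples present in both inputs are kept, in expression-column order.
    """
    mat = read_expression(expression_path, "dense_tsv", layer=layer)
    tab = read_survival_table(survival_path)
    shared = [s for s in mat.obs_ids if s in set(tab["sample_id"])]
    if not shared:
        raise ValidationError("no samples shared between expression and survival table")
    mat = mat.select_obs(shared)
    tab = tab.set_index("sample_id").loc[shared].reset_index()
    return SurvivalCohort(mat, tab)


def read_drug_table(path: str | Path) -> pd.DataFrame:
    """Read a samples x drugs AUC table (TSV, first column sample IDs)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(f"malformed GMT line: {line[:60]!r}")
            name, desc, genes = fields[0], fields[1], fields[2:]
            if name in sets:
                raise ValidationError(f"duplicate gene set name {name!r}")
            sets[name] = [g for g in genes if g]
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def load_risk_signatures() -> GeneSetCollection:
    """Load the published SPSM risk-gene list and the SPSM/IPSM shared genes.

    These ship with the package as a GMT file and back the signature-level
    survival and drug-screen examples.
    """
    ref = importlib.resources.files("tiprog.data") / "tnbc_risk_signatures.gmt"
    with importlib.resources.as_file(ref) as p:
        return read_gmt(p)
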