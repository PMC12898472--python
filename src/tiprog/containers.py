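"""Core in-memory containers shared by every pipeline stage.

The central object is :class:`ExpressionMatrix`, a genes x observations
matrix tagged with the transformation layer it carries (``counts``,
``lognorm`` or ``zscore``).  Cell metadata, gene annotation, survival
cohorts and drug-response tables are plain :class:`pandas.DataFrame`
objects with validated schemas; gene sets live in
:class:`GeneSetCollection` with GMT semantics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

LAYERS = ("counts", "lognorm", "zscore")

COMPARTMENTS = ("epithelial", "immune", "stromal", "other")


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


def _check_unique(ids: Iterable[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = sorted({i for i in ids if i in seen or seen.add(i)})
        raise ValidationError(f"duplicate {what}: {dup[:10]}")
    return ids


@dataclass
class ExpressionMatrix:
    """A genes x observations expression matrix with a layer tag.

    Parameters
    ----------
    gene_ids : list of str
        Unique row identifiers.
    obs_ids : list of str
        Unique column identifiers (cells or bulk samples).
    values : ndarray of shape (n_genes, n_obs)
        Non-negative for ``counts``; any real for other layers.
    layer : {"counts", "lognorm", "zscore"}
        Which transformation the values carry.
    """

    gene_ids: list[str]
    obs_ids: list[str]
    values: np.ndarray
    layer: str = "counts"

    def __post_init__(self) -> None:
        self.gene_ids = _check_unique(self.gene_ids, "gene IDs")
        self.obs_ids = _check_unique(self.obs_ids, "observation IDs")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.obs_ids)):
            raise ValidationError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.obs_ids)} observations"
            )
        if self.layer not in LAYERS:
            raise ValidationError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if self.layer == "counts":
            if np.any(self.values < 0):
                raise ValidationError("counts layer contains negative values")
            if not np.allclose(self.values, np.round(self.values)):
                raise ValidationError("counts layer contains non-integral values")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values must be finite")

    # -- convenience ---------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_obs(self) -> int:
        return len(self.obs_ids)

    def gene_index(self) -> pd.Index:
        return pd.Index(self.gene_ids)

    def obs_index(self) -> pd.Index:
        return pd.Index(self.obs_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.obs_ids)

    def subset_genes(self, keep: np.ndarray | list) -> "ExpressionMatrix":
        """Row subset; `keep` is a boolean mask or integer positions (order kept)."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return ExpressionMatrix(
            [self.gene_ids[i] for i in keep], list(self.obs_ids),
            self.values[keep, :], self.layer,
        )

    def subset_obs(self, keep: np.ndarray | list) -> "ExpressionMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return ExpressionMatrix(
            list(self.gene_ids), [self.obs_ids[i] for i in keep],
            self.values[:, keep], self.layer,
        )

    def select_obs(self, obs: Iterable[str]) -> "ExpressionMatrix":
        pos = {o: i for i, o in enumerate(self.obs_ids)}
        missing = [o for o in obs if o not in pos]
        if missing:
            raise ValidationError(f"observations not in matrix: {missing[:10]}")
        return self.subset_obs([pos[o] for o in obs])

    def with_values(self, values: np.ndarray, layer: str) -> "ExpressionMatrix":
        return ExpressionMatrix(list(self.gene_ids), list(self.obs_ids), values, layer)


def validate_cell_metadata(meta: pd.DataFrame, mat: ExpressionMatrix | None = None) -> pd.DataFrame:
    """Validate a cell metadata table.

    Required columns: ``cell_id``, ``patient_id``, ``compartment``; optional
    ``cluster_label`` and ``tissue``.  When ``mat`` is given every cell of the
    matrix must be annotated.
    """
    required = {"cell_id", "patient_id", "compartment"}
    missing = required - set(meta.columns)
    if missing:
        raise ValidationError(f"cell metadata missing columns: {sorted(missing)}")
    _check_unique(meta["cell_id"], "cell IDs")
    bad = set(meta["compartment"]) - set(COMPARTMENTS)
    if bad:
        raise ValidationError(f"unknown compartments: {sorted(bad)}; expected {COMPARTMENTS}")
    if mat is not None:
        absent = set(mat.obs_ids) - set(meta["cell_id"])
        if absent:
            raise ValidationError(f"cells without metadata: {sorted(absent)[:10]}")
    return meta


def validate_gene_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    """Validate gene -> (chromosome, start) annotation; 0-based starts."""
    required = {"gene_id", "chromosome", "start"}
    missing = required - set(ann.columns)
    if missing:
        raise ValidationError(f"gene annotation missing columns: {sorted(missing)}")
    _check_unique(ann["gene_id"], "annotated gene IDs")
    if (ann["start"] < 0).any():
        raise ValidationError("gene annotation contains negative start positions")
    return ann


@dataclass
class SurvivalCohort:
    """Bulk expression paired with right-censored overall survival.

    ``table`` columns: ``sample_id``, ``time`` (months, > 0), ``event``
    (0/1) plus optional covariate columns; sample order matches the
    expression matrix columns.
    """

    expression: ExpressionMatrix
    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "time", "event"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"survival table missing columns: {sorted(missing)}")
        _check_unique(self.table["sample_id"], "sample IDs")
        if (self.table["time"] <= 0).any():
            raise ValidationError("survival times must be positive")
        if not set(self.table["event"].unique()) <= {0, 1}:
            raise ValidationError("event indicator must be 0/1")
        if list(self.table["sample_id"]) != list(self.expression.obs_ids):
            raise ValidationError("survival table sample order must match expression columns")

    @property
    def time(self) -> np.ndarray:
        return self.table["time"].to_numpy(float)

    @property
    def event(self) -> np.ndarray:
        return self.table["event"].to_numpy(int)

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.table.columns if c not in ("sample_id", "time", "event")]


@dataclass
class GeneSetCollection(Mapping):
    """Named gene sets with GMT semantics (unique names, non-empty sets)."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")
            self.sets[name] = _check_unique(genes, f"genes in set {name!r}")

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)
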