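"""Core in-memory containers: count matrices, annotation tables, prediction records.

The expression substrate for every pipeline stage is a gene x cell matrix of
non-negative integer UMI counts, held here as :class:`CountMatrix` with genes
as rows and cells as columns regardless of the on-disk orientation. Real-valued
derived matrices (log-normalized, scaled) live in named ``layers`` of identical
shape and identical id ordering.

Per-cell labels are hierarchical: a cell type for every cell, and — only for
cardiomyocytes — an anatomical zone (atrial ``A`` vs ventricular ``V``) and a
laterality/side (left ``L`` vs right ``R``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import IntegrityError

__all__ = [
    "CountMatrix",
    "LabelVocabulary",
    "AnnotationTable",
    "PredictionRecord",
    "DEFAULT_VOCABULARY",
]


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(x) for x in ids]
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(x for x in ids if x in seen or seen.add(x))  # type: ignore[func-returns-value]
        raise IntegrityError(f"duplicate {what} id: {dup!r}")
    return ids


@dataclass
class CountMatrix:
    """Sparse-capable gene x cell matrix of non-negative integer counts.

    Parameters
    ----------
    gene_ids
        Unique gene identifiers (row labels). The canonical gene key; gene
        symbols, when known, are carried separately in ``gene_symbols``.
    cell_ids
        Unique cell barcodes / identifiers (column labels).
    counts
        ``(n_genes, n_cells)`` matrix of raw counts; stored as CSC sparse.
    layers
        Optional named real-valued matrices of identical shape and ordering,
        e.g. ``"lognorm"`` or ``"scaled"``.
    gene_symbols
        Optional per-gene symbols aligned with ``gene_ids`` (need not be
        unique); used e.g. by the mitochondrial-gene predicate in QC.
    """

    gene_ids: list[str]
    cell_ids: list[str]
    counts: sp.spmatrix
    layers: dict[str, np.ndarray | sp.spmatrix] = field(default_factory=dict)
    gene_symbols: list[str] | None = None

    def __post_init__(self) -> None:
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.cell_ids = _check_unique(self.cell_ids, "cell")
        counts = sp.csc_matrix(self.counts)
        if counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise IntegrityError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if counts.nnz and counts.data.min() < 0:
            raise IntegrityError("counts must be non-negative")
        if counts.nnz and np.any(counts.data != np.round(counts.data)):
            raise IntegrityError("counts must be integral")
        self.counts = counts
        for name, layer in self.layers.items():
            if layer.shape != counts.shape:
                raise IntegrityError(
                    f"layer {name!r} shape {layer.shape} != counts shape {counts.shape}"
                )
        if self.gene_symbols is not None and len(self.gene_symbols) != len(self.gene_ids):
            raise IntegrityError("gene_symbols length must match gene_ids")

    # -- basic geometry ---------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_genes, self.n_cells)

    # -- per-cell summaries ----------------------------------------------
    def library_sizes(self) -> np.ndarray:
        """Total counts per cell."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def genes_detected(self) -> np.ndarray:
        """Number of genes with at least one count, per cell."""
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()

    # -- subsetting -------------------------------------------------------
    def subset_genes(self, index: np.ndarray | Sequence[int]) -> "CountMatrix":
        index = np.asarray(index)
        return CountMatrix(
            gene_ids=[self.gene_ids[i] for i in index],
            cell_ids=list(self.cell_ids),
            counts=self.counts[index, :],
            layers={k: _take_rows(v, index) for k, v in self.layers.items()},
            gene_symbols=None
            if self.gene_symbols is None
            else [self.gene_symbols[i] for i in index],
        )

    def subset_cells(self, index: np.ndarray | Sequence[int]) -> "CountMatrix":
        index = np.asarray(index)
        return CountMatrix(
            gene_ids=list(self.gene_ids),
            cell_ids=[self.cell_ids[i] for i in index],
            counts=self.counts[:, index],
            layers={k: _take_cols(v, index) for k, v in self.layers.items()},
            gene_symbols=None if self.gene_symbols is None else list(self.gene_symbols),
        )

    def gene_index(self, genes: Iterable[str]) -> np.ndarray:
        """Positions of ``genes`` in this matrix; missing genes raise KeyError."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise KeyError(f"genes not present: {missing[:10]}")
        return np.array([lookup[g] for g in genes], dtype=int)

    def dense_counts(self) -> np.ndarray:
        return np.asarray(self.counts.todense())

    def layer_dense(self, name: str) -> np.ndarray:
        layer = self.layers[name]
        return np.asarray(layer.todense()) if sp.issparse(layer) else np.asarray(layer)


def _take_rows(m, index):
    return m[index, :] if sp.issparse(m) else np.asarray(m)[index, :]


def _take_cols(m, index):
    return m[:, index] if sp.issparse(m) else np.asarray(m)[:, index]


@dataclass(frozen=True)
class LabelVocabulary:
    """Declared category sets for hierarchical annotations.

    ``cm_label`` names the cardiomyocyte class — the only class for which zone
    and side are defined.
    """

    cell_types: frozenset[str]
    cm_label: str = "cm"
    zones: frozenset[str] = frozenset({"A", "V"})
    sides: frozenset[str] = frozenset({"L", "R"})

    def __post_init__(self) -> None:
        if self.cm_label not in self.cell_types:
            raise ValueError(
                f"cardiomyocyte label {self.cm_label!r} missing from cell_types"
            )


DEFAULT_VOCABULARY = LabelVocabulary(
    cell_types=frozenset({"cm", "f", "ec_endo", "ec_vasc", "ep", "v", "mf", "b/t", "5w"})
)


class AnnotationTable:
    """Validated per-cell hierarchical labels.

    Wraps a DataFrame indexed by unique ``cell_id`` with columns ``cell_type``,
    ``zone``, ``side`` (zone/side defined only for cardiomyocytes; missing
    elsewhere) plus arbitrary extra metadata columns.
    """

    REQUIRED = ("cell_type",)

    def __init__(
        self,
        df: pd.DataFrame,
        vocabulary: LabelVocabulary,
        strict: bool = True,
    ) -> None:
        df = df.copy()
        if "cell_id" in df.columns:
            df = df.set_index("cell_id")
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise IntegrityError(f"duplicate cell_id: {dup!r}")
        for col in self.REQUIRED:
            if col not in df.columns:
                from .errors import FormatError

                raise FormatError(f"missing required column {col!r}")
        for col in ("zone", "side"):
            if col not in df.columns:
                df[col] = pd.NA
        df["zone"] = df["zone"].replace({"": pd.NA})
        df["side"] = df["side"].replace({"": pd.NA})

        unknown = set(df["cell_type"].astype(str)) - set(vocabulary.cell_types)
        if unknown and strict:
            raise IntegrityError(f"unknown cell_type categories: {sorted(unknown)}")
        bad_zone = df["zone"].dropna().astype(str)
        bad_zone = set(bad_zone) - set(vocabulary.zones)
        if bad_zone:
            raise IntegrityError(f"unknown zone categories: {sorted(bad_zone)}")
        bad_side = set(df["side"].dropna().astype(str)) - set(vocabulary.sides)
        if bad_side:
            raise IntegrityError(f"unknown side categories: {sorted(bad_side)}")

        # zone/side are meaningful for cardiomyocytes only
        non_cm = df["cell_type"] != vocabulary.cm_label
        stray = non_cm & (df["zone"].notna() | df["side"].notna())
        if stray.any():
            warnings.warn(
                f"zone/side set for {int(stray.sum())} non-cardiomyocyte cells; "
                "coerced to missing",
                stacklevel=2,
            )
            df.loc[stray, ["zone", "side"]] = pd.NA

        self.df = df
        self.vocabulary = vocabulary

    @property
    def cell_ids(self) -> list[str]:
        return [str(x) for x in self.df.index]

    def cell_types(self) -> pd.Series:
        return self.df["cell_type"]

    def subset(self, cell_ids: Sequence[str]) -> "AnnotationTable":
        return AnnotationTable(
            self.df.loc[list(cell_ids)].reset_index(names="cell_id"),
            self.vocabulary,
            strict=False,
        )

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class PredictionRecord:
    """Per-cell hierarchical prediction with class probabilities.

    Zone/side fields are populated only when the predicted type is the
    cardiomyocyte label; after anomaly filtering, flagged cells carry no
    downstream labels.
    """

    cell_id: str
    predicted_type: str
    type_probability: float
    predicted_zone: str | None = None
    zone_probability: float | None = None
    predicted_side: str | None = None
    side_probability: float | None = None
    is_anomaly: bool = False

    def __post_init__(self) -> None:
        for p in (self.type_probability, self.zone_probability, self.side_probability):
            if p is not None and not (0.0 <= p <= 1.0):
                raise ValueError(f"probability {p} outside [0, 1]")


def records_to_frame(records: Sequence[PredictionRecord]) -> pd.DataFrame:
    """Prediction records as a DataFrame in the canonical column order."""
    rows = []
    for r in records:
        rows.append(
            {
                "cell_id": r.cell_id,
                "predicted_type": r.predicted_type,
                "type_probability": r.type_probability,
                "predicted_zone": r.predicted_zone,
                "zone_probability": r.zone_probability,
                "predicted_side": r.predicted_side,
                "side_probability": r.side_probability,
                "is_anomaly": r.is_anomaly,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cell_id",
            "predicted_type",
            "type_probability",
            "predicted_zone",
            "zone_probability",
            "predicted_side",
            "side_probability",
            "is_anomaly",
        ],
    )
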