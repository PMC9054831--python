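"""Readers and writers for the standard on-disk formats.

Count matrices travel as 10X CellRanger v3 style Matrix Market bundles
(``matrix.mtx[.gz]`` + ``barcodes.tsv[.gz]`` + ``features.tsv[.gz]``);
annotation and prediction tables as headered CSV/TSV. Gzip is handled
transparently for all bundle members. Internally matrices are always
gene-rows x cell-columns; a transposed MTX is detected from the TSV lengths
and converted.
"""

from __future__ import annotations

import gzip
import os
from pathlib import Path
from typing import Sequence

import pandas as pd
import scipy.io
import scipy.sparse as sp

from .core import AnnotationTable, CountMatrix, LabelVocabulary, PredictionRecord, records_to_frame
from .errors import FormatError, IntegrityError

__all__ = [
    "read_matrix_bundle",
    "write_matrix_bundle",
    "read_annotation_table",
    "write_prediction_table",
    "read_prediction_table",
]

_PROB_COLS = ("type_probability", "zone_probability", "side_probability")


def _find_member(directory: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        p = directory / name
        if p.exists():
            return p
    raise FormatError(f"bundle member {stem!r} not found in {directory}")


def _read_tsv_lines(path: Path) -> list[list[str]]:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt", encoding="utf-8") as fh:
        return [line.rstrip("\n").split("\t") for line in fh if line.strip()]


def read_matrix_bundle(path: str | os.PathLike) -> CountMatrix:
    """Read a 10X-style Matrix Market bundle into a :class:`CountMatrix`.

    ``path`` is a directory holding ``matrix.mtx``, ``barcodes.tsv`` and
    ``features.tsv`` (optionally gzipped). Gene and cell identifiers are taken
    from the TSVs in file order; counts are preserved exactly. The feature
    file's first column is the canonical gene id; a second column, if present,
    is kept as gene symbols.
    """
    directory = Path(path)
    if not directory.is_dir():
        raise FormatError(f"bundle directory not found: {directory}")
    mtx_path = _find_member(directory, "matrix.mtx")
    barcodes_path = _find_member(directory, "barcodes.tsv")
    features_path = _find_member(directory, "features.tsv")

    if mtx_path.suffix == ".gz":
        with gzip.open(mtx_path, "rb") as fh:
            counts = scipy.io.mmread(fh)
    else:
        counts = scipy.io.mmread(mtx_path)
    counts = sp.csc_matrix(counts)

    barcodes = [row[0] for row in _read_tsv_lines(barcodes_path)]
    feature_rows = _read_tsv_lines(features_path)
    gene_ids = [row[0] for row in feature_rows]
    gene_symbols = [row[1] if len(row) > 1 else row[0] for row in feature_rows]

    n_genes, n_cells = len(gene_ids), len(barcodes)
    if counts.shape == (n_genes, n_cells):
        pass
    elif counts.shape == (n_cells, n_genes) and n_genes != n_cells:
        counts = sp.csc_matrix(counts.T)
    else:
        raise IntegrityError(
            f"matrix.mtx declares shape {counts.shape} but features.tsv has "
            f"{n_genes} rows and barcodes.tsv has {n_cells} rows"
        )
    if len(set(barcodes)) != len(barcodes):
        raise IntegrityError("duplicate barcodes in barcodes.tsv")
    return CountMatrix(
        gene_ids=gene_ids, cell_ids=barcodes, counts=counts, gene_symbols=gene_symbols
    )


def write_matrix_bundle(matrix: CountMatrix, path: str | os.PathLike, gzipped: bool = False) -> None:
    """Write a :class:`CountMatrix` as a 10X-style bundle (inverse of the reader)."""
    directory = Path(path)
    directory.mkdir(parents=True, exist_ok=True)
    suffix = ".gz" if gzipped else ""

    mtx_path = directory / f"matrix.mtx{suffix}"
    coo = sp.coo_matrix(matrix.counts)
    if gzipped:
        with gzip.open(mtx_path, "wb") as fh:
            scipy.io.mmwrite(fh, coo, field="integer")
    else:
        scipy.io.mmwrite(str(mtx_path), coo, field="integer")

    def _write_tsv(name: str, rows: Sequence[str]) -> None:
        p = directory / f"{name}{suffix}"
        opener = gzip.open if gzipped else open
        with opener(p, "wt", encoding="utf-8") as fh:
            for row in rows:
                fh.write(row + "\n")

    _write_tsv("barcodes.tsv", matrix.cell_ids)
    symbols = matrix.gene_symbols or matrix.gene_ids
    _write_tsv(
        "features.tsv",
        [f"{gid}\t{sym}\tGene Expression" for gid, sym in zip(matrix.gene_ids, symbols)],
    )


def read_annotation_table(
    path: str | os.PathLike,
    vocabulary: LabelVocabulary,
    strict: bool = True,
) -> AnnotationTable:
    """Read and validate a per-cell annotation CSV/TSV.

    The file must have a header with ``cell_id`` and ``cell_type`` columns;
    ``zone``/``side`` are optional. Unknown cell types are rejected unless
    ``strict=False``; zone/side on non-cardiomyocyte rows are coerced to
    missing with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"annotation file not found: {path}")
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    if "cell_id" not in df.columns:
        raise FormatError("missing required column 'cell_id'")
    return AnnotationTable(df, vocabulary, strict=strict)


def write_prediction_table(records: Sequence[PredictionRecord], path: str | os.PathLike) -> None:
    """Write prediction records as CSV with a fixed column order.

    Missing zone/side fields are written as empty strings; probabilities are
    formatted to 6 decimal places so a read-back reproduces them to 1e-6.
    """
    df = records_to_frame(records)
    for col in _PROB_COLS:
        df[col] = df[col].map(lambda v: "" if pd.isna(v) else f"{float(v):.6f}")
    df["is_anomaly"] = df["is_anomaly"].map(lambda b: "true" if b else "false")
    df = df.fillna("")
    try:
        df.to_csv(path, index=False)
    except OSError as exc:
        raise FormatError(f"cannot write prediction table to {path}: {exc}") from exc


def read_prediction_table(path: str | os.PathLike) -> list[PredictionRecord]:
    """Read back a prediction CSV written by :func:`write_prediction_table`."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"prediction file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    records = []
    for _, row in df.iterrows():
        records.append(
            PredictionRecord(
                cell_id=row["cell_id"],
                predicted_type=row["predicted_type"],
                type_probability=float(row["type_probability"]),
                predicted_zone=row["predicted_zone"] or None,
                zone_probability=float(row["zone_probability"]) if row["zone_probability"] else None,
                predicted_side=row["predicted_side"] or None,
                side_probability=float(row["side_probability"]) if row["side_probability"] else None,
                is_anomaly=row["is_anomaly"] == "true",
            )
        )
    return records
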