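"""Cell- and gene-level quality control and log-normalization.

Cells are retained when total library size >= 2000 UMIs, the number of
detected genes lies in [1000, 8000] and the mitochondrial fraction is
<= 30% — all comparisons inclusive. Genes are retained when they carry at
least one count in at least five cells. Mitochondrial genes are identified
by a symbol prefix (default ``MT-``), configurable as a regex, since
annotation conventions differ between references.

Normalization uses per-cell library-size factors (library / mean library)
behind a pluggable ``method`` argument; pooled-deconvolution factors from
external toolchains can be slotted in by callers that have them — any
monotone per-cell scaling is compatible with the downstream feature
selection and scaling steps.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core import CountMatrix

__all__ = ["QCThresholds", "QCReport", "qc_filter_cells", "filter_genes", "log_normalize"]


@dataclass(frozen=True)
class QCThresholds:
    """Inclusive per-cell QC thresholds.

    Defaults match a permissive organoid scRNA-seq screen: library >= 2000
    UMIs, 1000 <= detected genes <= 8000, mitochondrial fraction <= 0.30.
    """

    min_library_size: int = 2000
    min_genes: int = 1000
    max_genes: int = 8000
    max_mito_fraction: float = 0.30
    mito_gene_pattern: str = r"^MT-"

    def __post_init__(self) -> None:
        if self.min_genes > self.max_genes:
            raise ValueError("min_genes must be <= max_genes")
        if not (0.0 <= self.max_mito_fraction <= 1.0):
            raise ValueError("max_mito_fraction must be in [0, 1]")


@dataclass
class QCReport:
    """Per-cell QC metrics with kept/removed flags and reason codes."""

    metrics: pd.DataFrame  # index cell_id; library_size, n_genes, mito_fraction, kept, reasons
    n_input: int
    n_kept: int

    @property
    def n_removed(self) -> int:
        return self.n_input - self.n_kept

    def summary(self) -> dict[str, int]:
        reasons = self.metrics.loc[~self.metrics["kept"], "reasons"]
        counts: dict[str, int] = {"input": self.n_input, "kept": self.n_kept}
        for code in ("library", "genes", "mito"):
            counts[f"removed_{code}"] = int(reasons.str.contains(code).sum())
        return counts


def _mito_mask(m: CountMatrix, pattern: str) -> np.ndarray:
    names = m.gene_symbols if m.gene_symbols is not None else m.gene_ids
    rx = re.compile(pattern)
    return np.array([bool(rx.search(name)) for name in names])


def qc_filter_cells(
    m: CountMatrix, thresholds: QCThresholds | None = None
) -> tuple[CountMatrix, QCReport]:
    """Filter cells on library size, detected genes and mitochondrial fraction.

    Retains exactly the cells satisfying every inclusive threshold; column
    order is preserved. An empty input returns an empty matrix and report.
    """
    t = thresholds or QCThresholds()
    library = m.library_sizes().astype(float)
    detected = m.genes_detected()
    mito = _mito_mask(m, t.mito_gene_pattern)
    mito_counts = np.asarray(m.counts[mito, :].sum(axis=0)).ravel() if mito.any() else np.zeros(m.n_cells)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(library > 0, mito_counts / np.maximum(library, 1e-300), 0.0)

    ok_library = library >= t.min_library_size
    ok_genes = (detected >= t.min_genes) & (detected <= t.max_genes)
    ok_mito = mito_frac <= t.max_mito_fraction
    kept = ok_library & ok_genes & ok_mito

    reasons = []
    for i in range(m.n_cells):
        codes = []
        if not ok_library[i]:
            codes.append("library")
        if not ok_genes[i]:
            codes.append("genes")
        if not ok_mito[i]:
            codes.append("mito")
        reasons.append(";".join(codes))

    metrics = pd.DataFrame(
        {
            "library_size": library.astype(int),
            "n_genes": detected,
            "mito_fraction": mito_frac,
            "kept": kept,
            "reasons": reasons,
        },
        index=pd.Index(m.cell_ids, name="cell_id"),
    )
    report = QCReport(metrics=metrics, n_input=m.n_cells, n_kept=int(kept.sum()))
    return m.subset_cells(np.flatnonzero(kept)), report


def filter_genes(m: CountMatrix, min_cells: int = 5, min_count: int = 1) -> CountMatrix:
    """Keep genes with count >= ``min_count`` in at least ``min_cells`` cells."""
    if min_cells <= 0:
        return m
    n_expressing = np.asarray((m.counts >= min_count).sum(axis=1)).ravel()
    return m.subset_genes(np.flatnonzero(n_expressing >= min_cells))


def log_normalize(m: CountMatrix, method: str = "library_size") -> CountMatrix:
    """Attach a ``"lognorm"`` layer of log1p library-size-normalized counts.

    Size factor for cell c is ``library_c / mean(library)``;
    ``lognorm = log(1 + count / size_factor)``. Cells with zero library get a
    size factor of 1 with a warning (their row stays all-zero anyway).
    """
    if method != "library_size":
        raise ValueError(f"unknown normalization method {method!r}")
    library = m.library_sizes().astype(float)
    if m.n_cells == 0:
        m.layers["lognorm"] = np.zeros(m.shape)
        return m
    mean_lib = library[library > 0].mean() if (library > 0).any() else 1.0
    factors = library / mean_lib
    zero = factors == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} cells with zero library size; size factor set to 1")
        factors[zero] = 1.0
    dense = m.dense_counts().astype(float)
    m.layers["lognorm"] = np.log1p(dense / factors[None, :])
    return m
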