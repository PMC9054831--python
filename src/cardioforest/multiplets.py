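"""Within- and between-sample multiplet estimation for MULTI-seq pools.

Sample barcoding identifies a droplet as a doublet only when its two cells
carry *different* sample barcodes; same-sample ("within-sample") doublets are
invisible to demultiplexing. Writing N_k for the number of cells called as
sample k, N = sum_k N_k, and D_b for the number of called between-sample
doublets, the fraction of doublets that is within-sample is modeled as
proportional to the abundance of the constituent cells:

    pi_w  ∝  sum_j N_j^2 / N^2        pi_b  ∝  sum_{i>j} N_i N_j / N^2

normalized so pi_w + pi_b = 1. Since the expected number of *observed*
doublets is D_b = N * p_m * pi_b, the overall doublet fraction is estimated as
p_m_hat = D_b / (N * pi_b) >= D_b / N, and the number of invisible
within-sample doublets still to flag is n_within = N * p_m_hat * pi_w.
Higher-order multiplets are assumed rare and ignored.

The default proportionality weights are exactly the ones above (self-pairs
counted as N_j^2, cross pairs unordered); a ``combinatorial`` variant using
C(N_j, 2) within-sample weights is available behind a flag.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping

import pandas as pd

from .errors import EstimationError

__all__ = [
    "MultiplexSummary",
    "MultipletEstimate",
    "summarize_sample_calls",
    "estimate_multiplet_fractions",
    "flag_within_sample_doublets",
]

DOUBLET_CALL = "doublet"
NEGATIVE_CALL = "negative"


@dataclass(frozen=True)
class MultiplexSummary:
    """Singlet tallies per sample plus the between-sample doublet count.

    ``n_negative`` cells (no confident barcode) are tracked but excluded from
    both N and D_b.
    """

    sample_counts: dict[str, int]
    d_between: int
    n_negative: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.sample_counts.values()) or self.d_between < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_cells(self) -> int:
        """N: total cells called as singlets (sum of per-sample counts)."""
        return sum(self.sample_counts.values())


@dataclass(frozen=True)
class MultipletEstimate:
    pi_within: float
    pi_between: float
    p_multiplet: float
    n_within: int


def summarize_sample_calls(calls: pd.Series | Mapping[str, str]) -> MultiplexSummary:
    """Tally a per-cell sample-call table (cell_id -> label/"doublet"/"negative")."""
    if not isinstance(calls, pd.Series):
        calls = pd.Series(dict(calls))
    if len(calls) == 0:
        raise EstimationError("empty sample-call table")
    labels = calls.astype(str)
    d_between = int((labels == DOUBLET_CALL).sum())
    n_negative = int((labels == NEGATIVE_CALL).sum())
    singlets = labels[(labels != DOUBLET_CALL) & (labels != NEGATIVE_CALL)]
    sample_counts = singlets.value_counts().to_dict()
    return MultiplexSummary(
        sample_counts={str(k): int(v) for k, v in sample_counts.items()},
        d_between=d_between,
        n_negative=n_negative,
    )


def pair_weights(sample_counts: Mapping[str, int], combinatorial: bool = False) -> tuple[int, int]:
    """Integer within/between pairing weights (sum N_j^2 resp. C(N_j,2); cross N_i N_j)."""
    counts = [int(v) for v in sample_counts.values()]
    if combinatorial:
        within = sum(n * (n - 1) // 2 for n in counts)
    else:
        within = sum(n * n for n in counts)
    total = sum(counts)
    between = (total * total - sum(n * n for n in counts)) // 2
    return within, between


def estimate_multiplet_fractions(
    summary: MultiplexSummary, combinatorial: bool = False
) -> MultipletEstimate:
    """Estimate pi_w, pi_b, the overall doublet fraction and the missing-within count.

    Exact rational arithmetic is used for the fractions; raises
    :class:`EstimationError` when only one sample has cells (pi_b = 0 makes
    the doublet fraction unidentifiable). A p_m_hat above 1 is reported as
    computed, with a warning.
    """
    n = summary.n_cells
    if n <= 0:
        raise EstimationError("no singlet-called cells; nothing to estimate")
    within_w, between_w = pair_weights(summary.sample_counts, combinatorial=combinatorial)
    if between_w == 0:
        raise EstimationError("between-sample fraction zero; p_m unidentifiable")
    pi_w = Fraction(within_w, within_w + between_w)
    pi_b = 1 - pi_w
    p_m = Fraction(summary.d_between) / (n * pi_b)
    if p_m > 1:
        warnings.warn(f"estimated multiplet fraction {float(p_m):.3f} exceeds 1")
    n_within_exact = n * p_m * pi_w
    # round half away from zero
    n_within = int(math.floor(n_within_exact + Fraction(1, 2)))
    return MultipletEstimate(
        pi_within=float(pi_w),
        pi_between=float(pi_b),
        p_multiplet=float(p_m),
        n_within=n_within,
    )


def flag_within_sample_doublets(
    scores: pd.Series | Mapping[str, float], estimate: MultipletEstimate
) -> set[str]:
    """Flag the ``n_within`` highest-scoring cells as within-sample doublets.

    ``scores`` maps cell_id to a doublet-likeness score (higher = more
    doublet-like), covering the cells not already called doublets. Ties are
    broken by lexicographic cell_id for determinism.
    """
    if not isinstance(scores, pd.Series):
        scores = pd.Series(dict(scores))
    k = estimate.n_within
    if k <= 0:
        return set()
    if k > len(scores):
        warnings.warn(
            f"n_within={k} exceeds the {len(scores)} scored cells; flagging all"
        )
        return set(str(c) for c in scores.index)
    order = sorted(scores.items(), key=lambda kv: (-float(kv[1]), str(kv[0])))
    return {str(cid) for cid, _ in order[:k]}
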