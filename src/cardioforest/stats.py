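"""Evaluation and reporting statistics.

Accuracy is the percentage of correctly classified cells; conditional
accuracy restricts the percentage to cells of one true label. Confusion
flows (true label, predicted label, count) are exported in long form, ready
for Sankey-style plotting. The cross-classification significance test is an
exact two-sided binomial test (minimum-likelihood summation, the convention
of R's ``binom.test``); group comparisons use Mann–Whitney rank tests with
Bonferroni adjustment; the differential-expression resampling design
repeatedly downsamples a cell population and re-counts significant genes so
that DEG counts can be compared across cell types of unequal abundance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import CardioforestError, ConfigError

__all__ = [
    "AccuracySummary",
    "accuracy_summary",
    "binomial_cross_test",
    "group_marker_test",
    "downsampled_deg_counts",
    "significance_stars",
]


@dataclass
class AccuracySummary:
    """Overall and per-class accuracies plus the confusion-flow table."""

    overall: float  # percent, 2-decimal precision
    conditional: dict[str, float]  # true label -> percent
    flows: pd.DataFrame  # columns: true, predicted, count
    n_cells: int


def accuracy_summary(truth: pd.Series, predicted: pd.Series) -> AccuracySummary:
    """Overall / conditional accuracies and the Sankey-ready flow table.

    Both series must be aligned by cell id (identical index sets) or plain
    equal-length sequences. Percentages are reported to 2 decimals.
    """
    truth = pd.Series(truth)
    predicted = pd.Series(predicted)
    if len(truth) != len(predicted):
        raise CardioforestError("truth and predicted have different lengths")
    if not truth.index.equals(predicted.index):
        if set(truth.index) != set(predicted.index):
            raise CardioforestError("truth and predicted ids do not match")
        predicted = predicted.loc[truth.index]
    if len(truth) == 0:
        raise CardioforestError("empty label vectors")

    flows = (
        pd.DataFrame({"true": truth.astype(str).values, "predicted": predicted.astype(str).values})
        .value_counts()
        .rename("count")
        .reset_index()
        .sort_values(["true", "predicted"], ignore_index=True)
    )
    correct = truth.astype(str).values == predicted.astype(str).values
    overall = round(100.0 * correct.mean(), 2)
    conditional = {}
    for label in sorted(set(truth.astype(str))):
        mask = truth.astype(str).values == label
        conditional[label] = round(100.0 * correct[mask].mean(), 2)
    return AccuracySummary(
        overall=overall, conditional=conditional, flows=flows, n_cells=len(truth)
    )


def binomial_cross_test(successes: int, trials: int, p0: float) -> float:
    """Exact two-sided binomial p-value by minimum-likelihood summation.

    Sums the probabilities of all outcomes no more likely than the observed
    one under Binomial(trials, p0).
    """
    if not (0 <= successes <= trials) or trials <= 0:
        raise ConfigError("need 0 <= successes <= trials with trials > 0")
    if not (0.0 < p0 < 1.0):
        raise ConfigError("p0 must lie in (0, 1)")
    return float(sps.binomtest(successes, trials, p0, alternative="two-sided").pvalue)


def significance_stars(p: float) -> str:
    """Map an adjusted p-value to the conventional star annotation."""
    if p <= 1e-4:
        return "****"
    if p <= 1e-3:
        return "***"
    if p <= 1e-2:
        return "**"
    if p <= 5e-2:
        return "*"
    return "ns"


def group_marker_test(
    expr: pd.DataFrame,
    groups: pd.Series,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Rank-based (Mann–Whitney) group comparisons with Bonferroni adjustment.

    ``expr`` is a genes x cells frame of log-normalized expression; ``groups``
    assigns each cell (column) a label. Every unordered group pair is compared
    per gene; the adjusted p is ``min(1, p * number of tests)``. Groups with
    fewer than 2 cells are skipped with a warning.
    """
    groups = pd.Series(groups).astype(str)
    if genes is None:
        genes = list(expr.index)
    labels = sorted(groups.unique())
    if len(labels) < 2:
        raise CardioforestError("need at least two groups")
    usable = []
    for g in labels:
        if (groups == g).sum() < 2:
            warnings.warn(f"group {g!r} has fewer than 2 cells; skipped")
        else:
            usable.append(g)
    pairs = list(combinations(usable, 2))
    n_tests = len(pairs) * len(genes)

    rows = []
    for a, b in pairs:
        xa = expr.loc[genes, groups[groups == a].index].to_numpy(dtype=float)
        xb = expr.loc[genes, groups[groups == b].index].to_numpy(dtype=float)
        res = sps.mannwhitneyu(xa, xb, axis=1, alternative="two-sided")
        for gi, gene in enumerate(genes):
            p = float(res.pvalue[gi])
            p_adj = min(1.0, p * n_tests)
            rows.append(
                {
                    "gene": gene,
                    "group_a": a,
                    "group_b": b,
                    "statistic": float(res.statistic[gi]),
                    "p_value": p,
                    "p_adjusted": p_adj,
                    "stars": significance_stars(p_adj),
                }
            )
    return pd.DataFrame(rows)


def downsampled_deg_counts(
    expr: np.ndarray | pd.DataFrame,
    condition: pd.Series | np.ndarray,
    target_n: int,
    n_reps: int = 200,
    fdr: float = 0.001,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Distribution of DEG counts under repeated downsampling.

    Each repetition samples ``target_n`` cells without replacement, preserving
    the two condition groups' proportions, runs a per-gene Mann–Whitney test
    between conditions with Benjamini–Hochberg correction, and counts genes
    significant at ``fdr``. Returns the ``n_reps`` counts and their median.
    """
    X = expr.to_numpy(dtype=float) if isinstance(expr, pd.DataFrame) else np.asarray(expr, dtype=float)
    condition = np.asarray(pd.Series(condition).astype(str))
    labels = np.unique(condition)
    if len(labels) != 2:
        raise ConfigError(f"need exactly two condition labels, got {list(labels)}")
    idx_a = np.flatnonzero(condition == labels[0])
    idx_b = np.flatnonzero(condition == labels[1])
    n_total = len(idx_a) + len(idx_b)
    if target_n > n_total:
        raise ConfigError(f"target_n={target_n} exceeds the {n_total} cells available")
    n_a = int(round(target_n * len(idx_a) / n_total))
    n_a = min(max(n_a, 1), target_n - 1)
    n_b = target_n - n_a

    rng = np.random.default_rng(np.random.SeedSequence([seed, 19]))
    counts = np.empty(n_reps, dtype=int)
    for rep in range(n_reps):
        sa = rng.choice(idx_a, size=n_a, replace=False)
        sb = rng.choice(idx_b, size=n_b, replace=False)
        res = sps.mannwhitneyu(X[:, sa], X[:, sb], axis=1, alternative="two-sided")
        reject, _, _, _ = multipletests(res.pvalue, alpha=fdr, method="fdr_bh")
        counts[rep] = int(reject.sum())
    return counts, float(np.median(counts))
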