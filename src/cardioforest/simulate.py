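"""Synthetic single-cell count data with known hierarchical ground truth.

The generator emulates the statistical structure the label-transfer method
assumes: hierarchically labelled cell populations (cell type; atrial/
ventricular zone and left/right side for cardiomyocytes only), platform-
specific depth / dropout / gene-wise scale effects between a reference and a
query dataset, and MULTI-seq style sample-barcoded pools containing doublets
and negatives.

Counts are drawn gene-wise from a negative binomial whose mean is a
long-tailed per-gene baseline multiplied by the applicable marker
fold-changes (type, then zone, then side for cardiomyocytes), then thinned
binomially to model dropout and scaled for sequencing depth. Marker effects
are ordered type > zone > side by default, reproducing the empirical
difficulty ordering of the three classification stages.

Everything is driven by `numpy.random.default_rng` seeded from the config, so
identical configs give identical data on any platform. Cell-group means (the
"biology") are derived from the config seed independently of the sampling
noise stream, so a query simulated from the same config shares the reference's
biology while its noise differs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core import AnnotationTable, CountMatrix, LabelVocabulary
from .errors import ConfigError
from .multiplets import pair_weights

__all__ = [
    "CellTypeSpec",
    "SubgroupSpec",
    "PlatformConfig",
    "PlatformShift",
    "SimulationConfig",
    "MultiplexConfig",
    "default_simulation_config",
    "simulate_reference",
    "simulate_query",
    "simulate_multiseq_experiment",
]


@dataclass(frozen=True)
class CellTypeSpec:
    """One cell type: its size, number of private marker genes and their effect."""

    n_cells: int
    n_markers: int
    fold_change: float

    def __post_init__(self) -> None:
        if self.n_cells < 0 or self.n_markers < 0 or self.fold_change <= 0:
            raise ConfigError("invalid cell-type spec")


@dataclass(frozen=True)
class SubgroupSpec:
    """A binary cardiomyocyte subdivision (zone A/V or side L/R)."""

    proportions: tuple[float, float] = (0.5, 0.5)
    n_markers: int = 30
    fold_change: float = 3.0

    def __post_init__(self) -> None:
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ConfigError("subgroup proportions must sum to 1")
        if self.fold_change <= 0:
            raise ConfigError("fold change must be positive")


@dataclass(frozen=True)
class PlatformConfig:
    """Technical characteristics of one platform/dataset."""

    depth_scale: float = 1.0
    dropout_rate: float = 0.1
    genewise_scale_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.depth_scale <= 0 or not (0.0 <= self.dropout_rate < 1.0):
            raise ConfigError("invalid platform config")


@dataclass(frozen=True)
class PlatformShift:
    """How a query platform differs from the reference.

    ``cell_fraction`` scales each reference group's size to set query group
    sizes; ``novel_type`` optionally injects a cell type absent from the
    reference (for anomaly-detection testing), specified as
    ``(name, CellTypeSpec)``.
    """

    platform: PlatformConfig = PlatformConfig(depth_scale=0.5, dropout_rate=0.2, genewise_scale_sd=0.3)
    cell_fraction: float = 0.75
    novel_type: tuple[str, CellTypeSpec] | None = None
    seed_offset: int = 104729  # decorrelates query noise from reference noise


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of a simulated reference dataset."""

    seed: int = 0
    n_genes: int = 2000
    cell_type_spec: Mapping[str, CellTypeSpec] = field(
        default_factory=lambda: {
            "cm": CellTypeSpec(200, 50, 8.0),
            "f": CellTypeSpec(200, 50, 8.0),
            "ec_endo": CellTypeSpec(200, 50, 8.0),
            "ep": CellTypeSpec(200, 50, 8.0),
        }
    )
    zone_spec: SubgroupSpec = SubgroupSpec(n_markers=30, fold_change=3.0)
    side_spec: SubgroupSpec = SubgroupSpec(n_markers=20, fold_change=1.8)
    baseline_log_mean: float = -0.7  # lognormal meanlog of per-gene baseline
    baseline_log_sd: float = 1.2  # long tail: a few high-expressed genes
    dispersion: float = 0.3  # NB overdispersion; variance = mu + dispersion * mu^2
    platform: PlatformConfig = PlatformConfig(depth_scale=1.0, dropout_rate=0.1, genewise_scale_sd=0.0)
    cm_label: str = "cm"

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or not self.cell_type_spec:
            raise ConfigError("need at least one gene and one cell type")
        if sum(s.n_cells for s in self.cell_type_spec.values()) <= 0:
            raise ConfigError("need at least one cell")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be non-negative")
        total_markers = sum(s.n_markers for s in self.cell_type_spec.values())
        total_markers += self.zone_spec.n_markers + self.side_spec.n_markers
        if total_markers > self.n_genes:
            raise ConfigError("more marker genes requested than genes simulated")


def default_simulation_config(seed: int = 0) -> SimulationConfig:
    """The default study conditions: 4 types x 200 cells, 2000 genes."""
    return SimulationConfig(seed=seed)


# ---------------------------------------------------------------------------
# biology: group mean construction (shared between reference and query)
# ---------------------------------------------------------------------------


def _biology(config: SimulationConfig):
    """Per-gene baselines, marker assignments and per-group mean vectors.

    Deterministic in ``config.seed`` and independent of the sampling noise
    stream, so reference and query share identical group means.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    baseline = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, config.n_genes)

    # assign disjoint marker blocks deterministically from the front of a
    # shuffled gene order
    order = rng.permutation(config.n_genes)
    cursor = 0
    type_markers: dict[str, np.ndarray] = {}
    for name in sorted(config.cell_type_spec):
        k = config.cell_type_spec[name].n_markers
        type_markers[name] = order[cursor : cursor + k]
        cursor += k
    zone_markers = order[cursor : cursor + config.zone_spec.n_markers]
    cursor += config.zone_spec.n_markers
    side_markers = order[cursor : cursor + config.side_spec.n_markers]
    cursor += config.side_spec.n_markers

    groups: list[tuple[str, str | None, str | None, np.ndarray]] = []
    for name in sorted(config.cell_type_spec):
        spec = config.cell_type_spec[name]
        mean = baseline.copy()
        mean[type_markers[name]] *= spec.fold_change
        if name == config.cm_label:
            # zone A up-regulates the first half of zone markers, V the second
            half_z = len(zone_markers) // 2
            half_s = len(side_markers) // 2
            for zone, z_idx in (("A", zone_markers[:half_z]), ("V", zone_markers[half_z:])):
                for side, s_idx in (("L", side_markers[:half_s]), ("R", side_markers[half_s:])):
                    m = mean.copy()
                    m[z_idx] *= config.zone_spec.fold_change
                    m[s_idx] *= config.side_spec.fold_change
                    groups.append((name, zone, side, m))
        else:
            groups.append((name, None, None, mean))
    return baseline, type_markers, order[cursor:], groups


def _sample_counts(
    rng: np.random.Generator,
    mean: np.ndarray,
    n_cells: int,
    dispersion: float,
    platform: PlatformConfig,
    gene_factors: np.ndarray,
) -> np.ndarray:
    """Draw an (n_genes, n_cells) count block for one homogeneous group."""
    mu = mean[:, None] * platform.depth_scale * gene_factors[:, None]
    mu = np.broadcast_to(mu, (len(mean), n_cells))
    if dispersion <= 1e-12:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / dispersion
        p = r / (r + mu)
        counts = rng.negative_binomial(r, p)
    if platform.dropout_rate > 0:
        counts = rng.binomial(counts, 1.0 - platform.dropout_rate)
    return counts


def _simulate_dataset(
    config: SimulationConfig,
    groups,
    group_sizes: list[int],
    platform: PlatformConfig,
    noise_seed: int,
    prefix: str,
) -> tuple[CountMatrix, AnnotationTable]:
    rng = np.random.default_rng(np.random.SeedSequence([noise_seed, 11]))
    gene_factors = (
        rng.lognormal(0.0, platform.genewise_scale_sd, config.n_genes)
        if platform.genewise_scale_sd > 0
        else np.ones(config.n_genes)
    )
    blocks, rows = [], []
    cell_counter = 0
    for (name, zone, side, mean), size in zip(groups, group_sizes):
        if size == 0:
            continue
        blocks.append(_sample_counts(rng, mean, size, config.dispersion, platform, gene_factors))
        for _ in range(size):
            rows.append(
                {
                    "cell_id": f"{prefix}{cell_counter:05d}",
                    "cell_type": name,
                    "zone": zone if zone is not None else "",
                    "side": side if side is not None else "",
                }
            )
            cell_counter += 1
    counts = np.concatenate(blocks, axis=1)
    gene_ids = [f"G{i:05d}" for i in range(config.n_genes)]
    matrix = CountMatrix(
        gene_ids=gene_ids,
        cell_ids=[r["cell_id"] for r in rows],
        counts=sp.csc_matrix(counts),
        gene_symbols=list(gene_ids),
    )
    vocab = LabelVocabulary(
        cell_types=frozenset({g[0] for g in groups} | {config.cm_label}),
        cm_label=config.cm_label,
    )
    ann = AnnotationTable(pd.DataFrame(rows), vocab, strict=True)
    return matrix, ann


def _group_sizes_reference(config: SimulationConfig, groups) -> list[int]:
    sizes = []
    for name, zone, side, _ in groups:
        spec = config.cell_type_spec[name]
        if zone is None:
            sizes.append(spec.n_cells)
        else:
            pz = config.zone_spec.proportions[0 if zone == "A" else 1]
            ps = config.side_spec.proportions[0 if side == "L" else 1]
            sizes.append(int(round(spec.n_cells * pz * ps)))
    return sizes


def simulate_reference(config: SimulationConfig) -> tuple[CountMatrix, AnnotationTable]:
    """Simulate an annotated reference dataset under ``config``.

    Returns a count matrix (genes x cells) and the matching annotation table
    with zone/side filled for cardiomyocytes. Deterministic in the seed.
    """
    _, _, _, groups = _biology(config)
    sizes = _group_sizes_reference(config, groups)
    return _simulate_dataset(config, groups, sizes, config.platform, config.seed, "ref_")


def simulate_query(
    config: SimulationConfig, shift: PlatformShift | None = None
) -> tuple[CountMatrix, AnnotationTable]:
    """Simulate a query dataset sharing the reference's biology.

    Group means are identical to :func:`simulate_reference` under the same
    ``config``; depth, dropout and gene-wise scale follow ``shift.platform``;
    group sizes are the reference sizes scaled by ``shift.cell_fraction``.
    A ``shift.novel_type`` adds cells of a type absent from the reference,
    with its own private markers drawn from unused genes.
    """
    shift = shift or PlatformShift()
    baseline, _, spare_genes, groups = _biology(config)
    sizes = [max(1, int(round(s * shift.cell_fraction))) for s in _group_sizes_reference(config, groups)]

    groups = list(groups)
    if shift.novel_type is not None:
        name, spec = shift.novel_type
        if name in config.cell_type_spec:
            raise ConfigError(f"novel type {name!r} already present in the reference")
        if spec.n_markers > len(spare_genes):
            raise ConfigError("not enough unused genes for novel-type markers")
        mean = baseline.copy()
        mean[spare_genes[: spec.n_markers]] *= spec.fold_change
        groups.append((name, None, None, mean))
        sizes.append(spec.n_cells)

    return _simulate_dataset(
        config, groups, sizes, shift.platform, config.seed + shift.seed_offset, "qry_"
    )


# ---------------------------------------------------------------------------
# MULTI-seq pools
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MultiplexConfig:
    """A sample-barcoded pool with doublets and negatives.

    ``doublet_rate`` is the expected number of doublet droplets relative to
    the number of singlet-*called* cells N (the denominator the estimator
    uses), so the estimator's p_m_hat is directly comparable to it.
    """

    seed: int = 0
    sample_sizes: Mapping[str, int] = field(default_factory=lambda: {"s1": 500, "s2": 500})
    doublet_rate: float = 0.1
    negative_rate: float = 0.02

    def __post_init__(self) -> None:
        if not self.sample_sizes:
            raise ConfigError("need at least one sample")
        if any(v < 0 for v in self.sample_sizes.values()):
            raise ConfigError("sample sizes must be non-negative")
        if not (0.0 <= self.doublet_rate < 1.0) or not (0.0 <= self.negative_rate < 1.0):
            raise ConfigError("rates must lie in [0, 1)")
        if self.doublet_rate + self.negative_rate >= 1.0:
            raise ConfigError("doublet_rate + negative_rate must be < 1")


def simulate_multiseq_experiment(config: MultiplexConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate demultiplexing calls for a barcoded pool.

    Singlets are called as their sample. Doublet composition follows the
    abundance ansatz the estimator assumes: an unordered pair of samples is
    drawn with weight ``N_j^2`` for a same-sample pair and ``N_i N_j`` for a
    cross pair. Cross-sample doublets are called ``"doublet"`` (detectable);
    same-sample doublets are called as their shared sample (undetectable);
    negatives are called ``"negative"``.

    Returns ``(calls, truth)``: calls with columns (cell_id, call); truth with
    columns (cell_id, kind in {singlet, doublet, negative}, sample_a,
    sample_b, within_sample).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 13]))
    samples = sorted(config.sample_sizes)
    sizes = np.array([config.sample_sizes[s] for s in samples], dtype=float)
    n_singlets = int(sizes.sum())
    if n_singlets == 0:
        raise ConfigError("no singlet cells configured")

    # number of doublets consistent with doublet_rate = n_d / N where
    # N = singlet calls = n_singlets + within-sample doublets
    within_w, between_w = pair_weights(dict(zip(samples, sizes.astype(int))))
    pi_w = within_w / (within_w + between_w) if (within_w + between_w) else 0.0
    n_doublets = int(round(config.doublet_rate * n_singlets / (1.0 - config.doublet_rate * pi_w)))
    n_negatives = int(round(config.negative_rate * n_singlets))

    rows_calls, rows_truth = [], []

    def add(cell_id: str, call: str, kind: str, a: str = "", b: str = "", within: bool = False):
        rows_calls.append({"cell_id": cell_id, "call": call})
        rows_truth.append(
            {"cell_id": cell_id, "kind": kind, "sample_a": a, "sample_b": b,
             "within_sample": within}
        )

    i = 0
    for s, n in zip(samples, sizes.astype(int)):
        for _ in range(n):
            add(f"bc{i:06d}", s, "singlet", a=s)
            i += 1

    if n_doublets > 0:
        # unordered pair categories with ansatz weights
        pair_labels: list[tuple[str, str]] = []
        weights: list[float] = []
        for j, sj in enumerate(samples):
            pair_labels.append((sj, sj))
            weights.append(sizes[j] * sizes[j])
            for k in range(j + 1, len(samples)):
                pair_labels.append((sj, samples[k]))
                weights.append(sizes[j] * sizes[k])
        probs = np.array(weights) / np.sum(weights)
        choices = rng.choice(len(pair_labels), size=n_doublets, p=probs)
        for c in choices:
            a, b = pair_labels[c]
            within = a == b
            add(f"bc{i:06d}", a if within else "doublet", "doublet", a, b, within)
            i += 1

    for _ in range(n_negatives):
        add(f"bc{i:06d}", "negative", "negative")
        i += 1

    return pd.DataFrame(rows_calls), pd.DataFrame(rows_truth)


def simulate_multiseq_counts(
    mux_config: MultiplexConfig,
    n_genes: int = 500,
    baseline_log_mean: float = -0.7,
    baseline_log_sd: float = 1.2,
    dispersion: float = 0.3,
) -> tuple[CountMatrix, pd.DataFrame, pd.DataFrame]:
    """A barcoded pool *with* expression: doublets are sums of two cell profiles.

    Generates the demultiplexing calls via :func:`simulate_multiseq_experiment`
    and a matching count matrix in which each singlet (and negative) droplet
    carries one simulated cell profile and each doublet carries the sum of two
    independent profiles — so doublets have roughly doubled library sizes,
    the signal crude score-based flagging exploits.

    Returns ``(matrix, calls, truth)``.
    """
    calls, truth = simulate_multiseq_experiment(mux_config)
    rng = np.random.default_rng(np.random.SeedSequence([mux_config.seed, 23]))
    baseline = rng.lognormal(baseline_log_mean, baseline_log_sd, n_genes)

    def one_profile(n: int) -> np.ndarray:
        r = 1.0 / dispersion
        mu = np.broadcast_to(baseline[:, None], (n_genes, n))
        return rng.negative_binomial(r, r / (r + mu))

    n_constituents = truth["kind"].map({"singlet": 1, "doublet": 2, "negative": 1}).to_numpy()
    profiles = one_profile(int(n_constituents.sum()))
    counts = np.empty((n_genes, len(truth)), dtype=np.int64)
    cursor = 0
    for j, n in enumerate(n_constituents):
        counts[:, j] = profiles[:, cursor : cursor + n].sum(axis=1)
        cursor += n
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    matrix = CountMatrix(
        gene_ids=gene_ids,
        cell_ids=list(truth["cell_id"]),
        counts=sp.csc_matrix(counts),
        gene_symbols=list(gene_ids),
    )
    return matrix, calls, truth
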