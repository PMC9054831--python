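"""Self-contained benchmark experiments on synthetic data.

These functions run the full pipeline end-to-end under the package's default
study conditions (4 cell types x 200 reference cells, 2000 genes, a query on
a shifted platform) and report the quantities a user would quote: hierarchical
transfer accuracies, anomaly-detection flag rates, and multiplet-rate
recovery. They are used by the example scripts and the acceptance harness.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import (
    MultiplexConfig,
    calibrate_thresholds,
    default_simulation_config,
    default_stage_configs,
    estimate_multiplet_fractions,
    filter_genes,
    log_normalize,
    predict_hierarchical,
    simulate_multiseq_experiment,
    simulate_query,
    simulate_reference,
    summarize_sample_calls,
    train_hierarchical,
)
from .simulate import CellTypeSpec, PlatformConfig, PlatformShift

__all__ = ["transfer_benchmark", "anomaly_benchmark", "multiplet_recovery_benchmark"]


def transfer_benchmark(seed: int) -> dict[str, float]:
    """Train on a simulated reference, predict a platform-shifted query.

    Returns the query type accuracy and the conditional zone/side accuracies
    on true cardiomyocytes that received the corresponding prediction.
    """
    cfg = default_simulation_config(seed=seed)
    ref, ann = simulate_reference(cfg)
    qry, qann = simulate_query(cfg)
    ref = filter_genes(log_normalize(ref))
    log_normalize(qry)
    model = train_hierarchical(ref, ann, qry, default_stage_configs(seed=seed))
    records = predict_hierarchical(model, qry)

    truth = qann.df
    pred_type = pd.Series({r.cell_id: r.predicted_type for r in records})
    pred_zone = pd.Series({r.cell_id: r.predicted_zone for r in records})
    pred_side = pd.Series({r.cell_id: r.predicted_side for r in records})
    out = {"type_accuracy": float((pred_type == truth["cell_type"]).mean())}
    cm = truth["cell_type"] == "cm"
    for name, pred in (("zone", pred_zone), ("side", pred_side)):
        mask = cm & pred.notna()
        out[f"{name}_conditional_accuracy"] = (
            float((pred[mask] == truth.loc[mask, name]).mean()) if mask.any() else float("nan")
        )
    return out


def anomaly_benchmark(seed: int) -> dict[str, float]:
    """Novel-cell-type rejection with thresholds from two simulated dev sets.

    The query contains 100 cells of an "immune" type absent from the
    reference; two development sets share the reference biology on distinct
    shifted platforms. Returns the fraction of novel cells flagged and the
    fraction of in-vocabulary cells flagged.
    """
    cfg = default_simulation_config(seed=seed)
    ref, ann = simulate_reference(cfg)
    novel = ("immune", CellTypeSpec(n_cells=100, n_markers=40, fold_change=8.0))
    qry, qann = simulate_query(cfg, PlatformShift(novel_type=novel))
    dev1, _ = simulate_query(
        cfg, PlatformShift(platform=PlatformConfig(0.7, 0.15, 0.2), seed_offset=200003)
    )
    dev2, _ = simulate_query(
        cfg, PlatformShift(platform=PlatformConfig(0.6, 0.25, 0.25), seed_offset=300007)
    )
    ref = filter_genes(log_normalize(ref))
    for m in (qry, dev1, dev2):
        log_normalize(m)
    model = train_hierarchical(ref, ann, qry, default_stage_configs(seed=seed))
    model.anomaly_thresholds = calibrate_thresholds(model, [(dev1, None), (dev2, None)])
    records = predict_hierarchical(model, qry)

    flags = pd.Series({r.cell_id: r.is_anomaly for r in records})
    novel_mask = qann.df["cell_type"] == "immune"
    return {
        "novel_flagged_fraction": float(flags[qann.df.index[novel_mask]].mean()),
        "known_flagged_fraction": float(flags[qann.df.index[~novel_mask]].mean()),
    }


def multiplet_recovery_benchmark(
    seed: int,
    n_replicates: int = 20,
    n_cells: int = 10_000,
    doublet_rate: float = 0.1,
) -> dict[str, float]:
    """Recover a configured doublet rate from simulated demultiplexing calls.

    Runs ``n_replicates`` independent pools of two equal samples and returns
    the mean estimated doublet fraction, its Monte-Carlo standard error, and
    the configured rate.
    """
    per_sample = n_cells // 2
    estimates = []
    for rep in range(n_replicates):
        mc = MultiplexConfig(
            seed=seed + rep,
            sample_sizes={"a": per_sample, "b": per_sample},
            doublet_rate=doublet_rate,
            negative_rate=0.02,
        )
        calls, _ = simulate_multiseq_experiment(mc)
        summary = summarize_sample_calls(pd.Series(calls["call"].values, index=calls["cell_id"]))
        estimates.append(estimate_multiplet_fractions(summary).p_multiplet)
    estimates = np.asarray(estimates)
    return {
        "configured_doublet_rate": doublet_rate,
        "estimated_doublet_rate": float(estimates.mean()),
        "mc_standard_error": float(estimates.std(ddof=1) / np.sqrt(n_replicates)),
    }
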