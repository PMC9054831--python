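"""Shared fixtures: tiny matrices and the reusable label-transfer experiment."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import cardioforest as cf
from cardioforest.simulate import CellTypeSpec, PlatformConfig, PlatformShift


def make_matrix(counts, gene_ids=None, cell_ids=None, gene_symbols=None):
    counts = np.asarray(counts)
    n_genes, n_cells = counts.shape
    return cf.CountMatrix(
        gene_ids=gene_ids or [f"g{i}" for i in range(n_genes)],
        cell_ids=cell_ids or [f"c{i}" for i in range(n_cells)],
        counts=sp.csc_matrix(counts),
        gene_symbols=gene_symbols,
    )


@pytest.fixture
def toy_matrix():
    return make_matrix([[1, 0], [2, 3], [0, 5]])


@pytest.fixture(scope="session")
def vocabulary():
    return cf.DEFAULT_VOCABULARY


@pytest.fixture(scope="session")
def anomaly_experiment():
    """One full transfer + anomaly calibration run with a novel query cell type.

    Reference and two development sets share the reference biology on shifted
    platforms; the query contains 100 cells of an "immune" type the reference
    never saw. Session-scoped: several tests inspect different aspects.
    """
    cfg = cf.default_simulation_config(seed=1)
    ref, ann = cf.simulate_reference(cfg)
    novel = ("immune", CellTypeSpec(n_cells=100, n_markers=40, fold_change=8.0))
    qry, qann = cf.simulate_query(cfg, PlatformShift(novel_type=novel))
    dev1, dev1_ann = cf.simulate_query(
        cfg, PlatformShift(platform=PlatformConfig(0.7, 0.15, 0.2), seed_offset=200003)
    )
    dev2, dev2_ann = cf.simulate_query(
        cfg, PlatformShift(platform=PlatformConfig(0.6, 0.25, 0.25), seed_offset=300007)
    )
    ref = cf.filter_genes(cf.log_normalize(ref))
    for m in (qry, dev1, dev2):
        cf.log_normalize(m)
    model = cf.train_hierarchical(ref, ann, qry, cf.default_stage_configs(seed=1))
    thresholds = cf.calibrate_thresholds(model, [(dev1, None), (dev2, None)])
    model.anomaly_thresholds = thresholds
    records = cf.predict_hierarchical(model, qry)
    return {
        "model": model,
        "thresholds": thresholds,
        "records": records,
        "query_truth": qann.df,
        "dev1": dev1,
        "dev2": dev2,
    }
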