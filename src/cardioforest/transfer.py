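"""Hierarchical random-forest label transfer across scRNA-seq datasets.

The method annotates query ("test") cells using an annotated reference
("train") dataset, typically produced on a different platform, in three
stacked stages:

1. **type** — cell type, trained on all reference cells;
2. **zone** — atrial (A) vs ventricular (V), trained on reference
   cardiomyocytes only and applied to query cells predicted as
   cardiomyocytes;
3. **side** — left (L) vs right (R), likewise cardiomyocyte-only, with an
   additional quantile-normalization step between feature selection and
   scaling.

Each stage runs independent highly-variable-gene selection on train and test
(top 50% by CV^2 excess over a fitted mean–CV^2 trend, after dropping genes
detected in fewer than a quarter of cells) and intersects the surviving sets.
Each dataset is then scaled *independently* per gene — subtract the minimum,
divide by the 95th percentile — which is what aligns the two platforms; no
map is transferred from train to test. A first forest with balanced class
weights ranks genes by impurity importance; a second, final forest is fit on
the top-ranked panel and produces per-class probabilities for prediction and
downstream anomaly detection.

Stage hyperparameter defaults are 300 trees / 500 genes (type),
300 / 100 (zone) and 500 / 100 (side).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.ensemble import RandomForestClassifier

from .core import AnnotationTable, CountMatrix, PredictionRecord
from .errors import CardioforestError, ConfigError
from .qc import log_normalize

__all__ = [
    "StageConfig",
    "ScalingRecord",
    "TrainedStage",
    "HierarchicalClassifier",
    "default_stage_configs",
    "select_features",
    "scale_matrix",
    "quantile_normalize",
    "quantile_map",
    "train_stage",
    "predict_stage",
    "train_hierarchical",
    "predict_hierarchical",
    "cross_validate",
    "tune_hyperparameter",
]

STAGES = ("type", "zone", "side")


@dataclass(frozen=True)
class StageConfig:
    """Hyperparameters for one classification stage."""

    stage: str
    n_trees: int
    n_top_genes: int
    quantile_normalize: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ConfigError(f"unknown stage {self.stage!r}")
        if self.n_trees < 1 or self.n_top_genes < 1:
            raise ConfigError("n_trees and n_top_genes must be >= 1")


def default_stage_configs(seed: int = 0) -> dict[str, StageConfig]:
    """Default per-stage hyperparameters (type 300/500, zone 300/100, side 500/100)."""
    return {
        "type": StageConfig("type", n_trees=300, n_top_genes=500, seed=seed),
        "zone": StageConfig("zone", n_trees=300, n_top_genes=100, seed=seed),
        "side": StageConfig("side", n_trees=500, n_top_genes=100, quantile_normalize=True, seed=seed),
    }


@dataclass
class ScalingRecord:
    """Per-gene scaling parameters of one dataset: min and 95th percentile."""

    dataset: str
    genes: list[str]
    minimum: np.ndarray
    q95: np.ndarray  # 95th percentile of the min-subtracted values


@dataclass
class TrainedStage:
    """One trained stage: selected feature panel plus the final forest."""

    stage: str
    selected_genes: list[str]  # intersected HVG set the stage operates on
    feature_genes: list[str]  # top-importance panel the final forest uses
    forest: RandomForestClassifier
    class_labels: list[str]
    seed: int
    qn_reference: np.ndarray | None = None  # pooled quantile profile (side stage)

    def predict(self, scaled: np.ndarray, gene_ids: list[str]) -> tuple[np.ndarray, pd.DataFrame]:
        return predict_stage(self, scaled, gene_ids)


@dataclass
class HierarchicalClassifier:
    """Three stacked stages plus optional per-class anomaly thresholds."""

    type_stage: TrainedStage
    zone_stage: TrainedStage | None
    side_stage: TrainedStage | None
    cm_label: str
    anomaly_thresholds: "object | None" = None  # anomaly.AnomalyThresholds


# ---------------------------------------------------------------------------
# feature selection
# ---------------------------------------------------------------------------


def _hvg_one_dataset(
    m: CountMatrix,
    detection_fraction: float,
    top_fraction: float,
) -> set[str]:
    """Highly variable genes of one dataset by CV^2 excess over a 1/mean trend."""
    lognorm = m.layer_dense("lognorm")
    detected = np.asarray((m.counts > 0).sum(axis=1)).ravel() / max(m.n_cells, 1)
    mask = detected >= detection_fraction
    if not mask.any():
        return set()
    vals = lognorm[mask, :]
    mean = vals.mean(axis=1)
    var = vals.var(axis=1, ddof=1) if m.n_cells > 1 else np.zeros(vals.shape[0])
    positive = mean > 0
    idx = np.flatnonzero(mask)[positive]
    mean, var = mean[positive], var[positive]
    cv2 = var / mean**2

    # robust fit of cv2 = a + b / mean
    exog = sm.add_constant(1.0 / mean)
    try:
        fit = sm.RLM(cv2, exog, M=sm.robust.norms.HuberT()).fit()
        fitted = fit.fittedvalues
    except Exception:  # degenerate toy inputs: fall back to OLS
        fitted = sm.OLS(cv2, exog).fit().fittedvalues
    fitted = np.maximum(fitted, 1e-12)
    ratio = cv2 / fitted

    n_keep = len(ratio) // 2
    if n_keep == 0:
        n_keep = len(ratio)
    gene_ids = [m.gene_ids[i] for i in idx]
    order = sorted(range(len(ratio)), key=lambda i: (-ratio[i], gene_ids[i]))
    return {gene_ids[i] for i in order[:n_keep]}


def select_features(
    train: CountMatrix,
    test: CountMatrix,
    detection_fraction: float = 0.25,
    top_fraction: float = 0.5,
) -> list[str]:
    """Shared highly-variable-gene panel of two log-normalized datasets.

    Selection runs independently on train and test (detection filter, then the
    top half of genes by CV^2 excess over the fitted trend); the intersection
    is returned in train gene order.
    """
    train_set = _hvg_one_dataset(train, detection_fraction, top_fraction)
    test_set = _hvg_one_dataset(test, detection_fraction, top_fraction)
    shared = [g for g in train.gene_ids if g in train_set and g in test_set]
    if not shared:
        raise CardioforestError(
            "no shared highly variable genes between train and test; "
            "relax detection_fraction or top_fraction"
        )
    return shared


# ---------------------------------------------------------------------------
# scaling and quantile normalization
# ---------------------------------------------------------------------------


def scale_matrix(
    m: CountMatrix, genes: list[str], dataset: str = "", layer: str = "lognorm"
) -> tuple[np.ndarray, ScalingRecord]:
    """Per-gene min-subtraction / 95th-percentile scaling of one dataset.

    For each gene: ``v' = (v - min(v)) / q95(v - min(v))`` with the percentile
    computed by linear interpolation between order statistics. A degenerate
    gene (q95 = 0) scales to all zeros. Scaling is per dataset — a train
    record is never applied to test data.
    """
    idx = m.gene_index(genes)
    vals = m.layer_dense(layer)[idx, :].astype(float)
    return _scale_values(vals, genes, dataset)


def _scale_values(vals: np.ndarray, genes: list[str], dataset: str = "") -> tuple[np.ndarray, ScalingRecord]:
    minimum = vals.min(axis=1)
    shifted = vals - minimum[:, None]
    q95 = np.quantile(shifted, 0.95, axis=1)
    safe = np.where(q95 > 0, q95, 1.0)
    scaled = shifted / safe[:, None]
    scaled[q95 == 0, :] = 0.0
    return scaled, ScalingRecord(dataset=dataset, genes=list(genes), minimum=minimum, q95=q95)


def quantile_normalize(matrices: list[np.ndarray]) -> tuple[list[np.ndarray], np.ndarray]:
    """Quantile-normalize cells of several matrices over a shared gene set.

    The reference profile is the mean sorted value vector pooled across all
    cells of all matrices; every cell's values are replaced by the reference
    values at their within-cell ranks (stable order for ties), so afterwards
    every cell's sorted vector is identical. Returns the transformed matrices
    and the reference profile.
    """
    if len(matrices) < 1:
        raise CardioforestError("need at least one matrix")
    n_genes = matrices[0].shape[0]
    if any(m.shape[0] != n_genes for m in matrices):
        raise CardioforestError("gene-set mismatch between matrices")
    pooled = np.concatenate([np.asarray(m, dtype=float) for m in matrices], axis=1)
    reference = np.sort(pooled, axis=0).mean(axis=1)
    return [quantile_map(m, reference) for m in matrices], reference


def quantile_map(matrix: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Map each column's values onto ``reference`` at their within-column ranks."""
    matrix = np.asarray(matrix, dtype=float)
    out = np.empty_like(matrix)
    for c in range(matrix.shape[1]):
        order = np.argsort(matrix[:, c], kind="stable")
        out[order, c] = reference
    return out


# ---------------------------------------------------------------------------
# forests
# ---------------------------------------------------------------------------


def _fit_forest(X: np.ndarray, labels: np.ndarray, n_trees: int, seed: int) -> RandomForestClassifier:
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        class_weight="balanced",
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X, labels)
    return forest


def train_stage(
    train_scaled: np.ndarray,
    gene_ids: list[str],
    labels: np.ndarray | pd.Series,
    cfg: StageConfig,
    qn_reference: np.ndarray | None = None,
) -> TrainedStage:
    """Two-round forest training: importance-based panel selection, then refit.

    A first forest with ``cfg.n_trees`` trees and balanced class weights is
    fit on all genes; genes are ranked by impurity importance (ties broken by
    gene id) and the top ``cfg.n_top_genes`` retained; the final forest is fit
    on that panel only. Deterministic given the seed.
    """
    labels = np.asarray(labels, dtype=object).astype(str)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise CardioforestError("need at least two classes to train a stage")
    small = classes[counts < 2]
    if len(small):
        raise CardioforestError(f"class {small[0]!r} has fewer than 2 cells")
    X = np.asarray(train_scaled, dtype=float).T  # cells x genes

    forest1 = _fit_forest(X, labels, cfg.n_trees, cfg.seed)
    importance = forest1.feature_importances_
    n_top = cfg.n_top_genes
    if n_top > len(gene_ids):
        warnings.warn(
            f"n_top_genes={n_top} exceeds the {len(gene_ids)} available genes; using all"
        )
        n_top = len(gene_ids)
    order = sorted(range(len(gene_ids)), key=lambda i: (-importance[i], gene_ids[i]))
    top_idx = order[:n_top]
    feature_genes = [gene_ids[i] for i in top_idx]

    forest2 = _fit_forest(X[:, top_idx], labels, cfg.n_trees, cfg.seed)
    return TrainedStage(
        stage=cfg.stage,
        selected_genes=list(gene_ids),
        feature_genes=feature_genes,
        forest=forest2,
        class_labels=[str(c) for c in forest2.classes_],
        seed=cfg.seed,
        qn_reference=qn_reference,
    )


def predict_stage(
    stage: TrainedStage, scaled: np.ndarray, gene_ids: list[str]
) -> tuple[np.ndarray, pd.DataFrame]:
    """Predict labels and per-class probabilities for scaled test cells.

    ``scaled`` is genes x cells over ``gene_ids``, which must contain every
    feature gene of the stage (missing genes raise, never silently zero-fill).
    Argmax ties break by class-name order.
    """
    lookup = {g: i for i, g in enumerate(gene_ids)}
    missing = [g for g in stage.feature_genes if g not in lookup]
    if missing:
        raise CardioforestError(f"test data missing feature genes: {missing[:10]}")
    idx = [lookup[g] for g in stage.feature_genes]
    X = np.asarray(scaled, dtype=float)[idx, :].T
    proba = stage.forest.predict_proba(X)
    # classes_ is lexicographically sorted; argmax returns the first maximum,
    # giving the tie-break by class name
    labels = np.array([stage.class_labels[i] for i in np.argmax(proba, axis=1)])
    table = pd.DataFrame(proba, columns=stage.class_labels)
    return labels, table


# ---------------------------------------------------------------------------
# hierarchical training / prediction
# ---------------------------------------------------------------------------


def _ensure_lognorm(m: CountMatrix) -> CountMatrix:
    if "lognorm" not in m.layers:
        log_normalize(m)
    return m


def _stage_train_matrix(
    train: CountMatrix,
    test: CountMatrix,
    labels: np.ndarray,
    cfg: StageConfig,
) -> TrainedStage:
    genes = select_features(train, test)
    qn_reference = None
    if cfg.quantile_normalize:
        train_vals = train.layer_dense("lognorm")[train.gene_index(genes), :]
        test_vals = test.layer_dense("lognorm")[test.gene_index(genes), :]
        (train_qn, _test_qn), qn_reference = quantile_normalize([train_vals, test_vals])
        scaled, _ = _scale_values(train_qn, genes, dataset="train")
    else:
        scaled, _ = scale_matrix(train, genes, dataset="train")
    return train_stage(scaled, genes, labels, cfg, qn_reference=qn_reference)


def train_hierarchical(
    train: CountMatrix,
    annotations: AnnotationTable,
    test: CountMatrix,
    cfgs: dict[str, StageConfig] | None = None,
) -> HierarchicalClassifier:
    """Train the type -> zone -> side stack against a given test gene space.

    The type stage uses all annotated training cells; zone and side stages use
    training cardiomyocytes only; the side stage quantile-normalizes train and
    test jointly (storing the pooled reference profile) between feature
    selection and scaling. The test matrix participates only in per-stage
    feature-set intersection — its expression values never enter training.
    """
    cfgs = cfgs or default_stage_configs()
    _ensure_lognorm(train)
    _ensure_lognorm(test)
    ann = annotations.df.loc[train.cell_ids]
    cm_label = annotations.vocabulary.cm_label

    type_stage = _stage_train_matrix(
        train, test, ann["cell_type"].to_numpy(), cfgs["type"]
    )

    cm_mask = (ann["cell_type"] == cm_label).to_numpy()
    zone_stage = side_stage = None
    if not cm_mask.any():
        warnings.warn("no cardiomyocytes in training data; zone/side stages skipped")
    else:
        train_cm = train.subset_cells(np.flatnonzero(cm_mask))
        ann_cm = ann.loc[cm_mask]
        for stage_name in ("zone", "side"):
            stage_labels = ann_cm[stage_name]
            usable = stage_labels.notna().to_numpy()
            if usable.sum() < 2 or stage_labels[usable].nunique() < 2:
                warnings.warn(
                    f"training cardiomyocytes lack usable {stage_name} labels; stage skipped"
                )
                continue
            sub = train_cm.subset_cells(np.flatnonzero(usable)) if not usable.all() else train_cm
            stage = _stage_train_matrix(
                sub, test, stage_labels[usable].astype(str).to_numpy(), cfgs[stage_name]
            )
            if stage_name == "zone":
                zone_stage = stage
            else:
                side_stage = stage

    return HierarchicalClassifier(
        type_stage=type_stage,
        zone_stage=zone_stage,
        side_stage=side_stage,
        cm_label=cm_label,
    )


def _stage_test_scaled(stage: TrainedStage, test: CountMatrix) -> np.ndarray:
    """Scale the test dataset for one stage (self-scaled; QN first if stored)."""
    vals = test.layer_dense("lognorm")[test.gene_index(stage.selected_genes), :]
    if stage.qn_reference is not None:
        vals = quantile_map(vals, stage.qn_reference)
    scaled, _ = _scale_values(vals, stage.selected_genes, dataset="test")
    return scaled


def predict_hierarchical(
    model: HierarchicalClassifier, test: CountMatrix
) -> list[PredictionRecord]:
    """Predict type for all test cells; zone/side for predicted cardiomyocytes.

    Anomaly flags are attached when the model carries calibrated thresholds;
    flagged cells keep their type call but lose zone/side labels.
    """
    _ensure_lognorm(test)
    type_scaled = _stage_test_scaled(model.type_stage, test)
    type_labels, type_proba = predict_stage(model.type_stage, type_scaled, model.type_stage.selected_genes)
    type_p = type_proba.to_numpy().max(axis=1)
    # probability OF the predicted class (argmax ties give the same value)
    records = [
        PredictionRecord(cell_id=cid, predicted_type=t, type_probability=float(p))
        for cid, t, p in zip(test.cell_ids, type_labels, type_p)
    ]

    cm_idx = np.flatnonzero(type_labels == model.cm_label)
    for stage, zone_field in ((model.zone_stage, "zone"), (model.side_stage, "side")):
        if stage is None or len(cm_idx) == 0:
            continue
        scaled = _stage_test_scaled(stage, test)[:, cm_idx]
        labels, proba = predict_stage(stage, scaled, stage.selected_genes)
        p = proba.to_numpy().max(axis=1)
        for j, i in enumerate(cm_idx):
            if zone_field == "zone":
                records[i].predicted_zone = str(labels[j])
                records[i].zone_probability = float(p[j])
            else:
                records[i].predicted_side = str(labels[j])
                records[i].side_probability = float(p[j])

    if model.anomaly_thresholds is not None:
        from .anomaly import apply_anomaly_filter

        records, _ = apply_anomaly_filter(records, model.anomaly_thresholds)
    return records


# ---------------------------------------------------------------------------
# cross-validation and tuning
# ---------------------------------------------------------------------------


def _stratified_folds(labels: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Fold assignment stratified by label, seeded; returns fold index per cell."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    folds = np.empty(len(labels), dtype=int)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < k:
            warnings.warn(f"class {cls!r} has fewer than {k} cells; folds unbalanced")
        rng.shuffle(idx)
        folds[idx] = np.arange(len(idx)) % k
    return folds


def cross_validate(
    data: CountMatrix,
    annotations: AnnotationTable,
    k: int = 10,
    cfgs: dict[str, StageConfig] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Stratified k-fold cross-validation of the hierarchical classifier.

    Every cell is predicted exactly once (by the model trained on the other
    folds). Returns a per-fold table plus a pooled row with overall type
    accuracy and conditional zone/side accuracies on true cardiomyocytes that
    received the corresponding prediction.
    """
    if k < 2:
        raise ConfigError("k must be >= 2")
    if k > data.n_cells:
        raise ConfigError(f"k={k} exceeds the {data.n_cells} cells available")
    ann = annotations.df.loc[data.cell_ids]
    labels = ann["cell_type"].to_numpy().astype(str)
    folds = _stratified_folds(labels, k, seed)

    rows = []
    all_records: dict[str, PredictionRecord] = {}
    for fold in range(k):
        test_idx = np.flatnonzero(folds == fold)
        train_idx = np.flatnonzero(folds != fold)
        train_m = data.subset_cells(train_idx)
        test_m = data.subset_cells(test_idx)
        train_ann = annotations.subset([data.cell_ids[i] for i in train_idx])
        model = train_hierarchical(train_m, train_ann, test_m, cfgs)
        records = predict_hierarchical(model, test_m)
        for r in records:
            all_records[r.cell_id] = r
        rows.append({"fold": fold, **_accuracy_row(records, ann, annotations.vocabulary.cm_label)})

    pooled = _accuracy_row(list(all_records.values()), ann, annotations.vocabulary.cm_label)
    rows.append({"fold": "pooled", **pooled})
    return pd.DataFrame(rows)


def _accuracy_row(records: list[PredictionRecord], ann: pd.DataFrame, cm_label: str) -> dict:
    pred = pd.DataFrame(
        {
            "predicted_type": [r.predicted_type for r in records],
            "predicted_zone": [r.predicted_zone for r in records],
            "predicted_side": [r.predicted_side for r in records],
        },
        index=[r.cell_id for r in records],
    )
    truth = ann.loc[pred.index]
    type_acc = float((pred["predicted_type"] == truth["cell_type"]).mean())
    out = {"type_accuracy": type_acc, "n_cells": len(pred)}
    for col, pcol in (("zone", "predicted_zone"), ("side", "predicted_side")):
        mask = (truth["cell_type"] == cm_label) & truth[col].notna() & pred[pcol].notna()
        out[f"{col}_conditional_accuracy"] = (
            float((pred.loc[mask, pcol] == truth.loc[mask, col]).mean()) if mask.any() else np.nan
        )
        out[f"n_{col}"] = int(mask.sum())
    return out


def tune_hyperparameter(
    data: CountMatrix,
    annotations: AnnotationTable,
    parameter: str,
    grid: list[int],
    cfgs: dict[str, StageConfig] | None = None,
    stage: str = "type",
    seed: int = 0,
    holdout_fraction: float = 0.3,
    tolerance: float = 0.005,
) -> tuple[pd.DataFrame, int]:
    """Accuracy-vs-value sweep with an explicit elbow rule.

    One seeded stratified holdout split is reused across the grid; for each
    value the stage is retrained with that value substituted and scored on the
    holdout. The elbow is the smallest grid value whose marginal accuracy gain
    to the next value is at most ``tolerance`` (default half a percentage
    point) — the computable stand-in for a visual elbow; if accuracy keeps
    climbing by more than the tolerance everywhere, the largest value wins.
    """
    if parameter not in ("n_trees", "n_top_genes"):
        raise ConfigError(f"unknown parameter {parameter!r}")
    if len(grid) < 2:
        raise ConfigError("grid must contain at least two values")
    if sorted(grid) != list(grid):
        raise ConfigError("grid must be sorted ascending")
    cfgs = dict(cfgs or default_stage_configs())

    ann = annotations.df.loc[data.cell_ids]
    labels = ann["cell_type"].to_numpy().astype(str)
    k = max(2, int(round(1.0 / holdout_fraction)))
    folds = _stratified_folds(labels, k, seed)
    test_idx = np.flatnonzero(folds == 0)
    train_idx = np.flatnonzero(folds != 0)
    train_m = data.subset_cells(train_idx)
    test_m = data.subset_cells(test_idx)
    train_ann = annotations.subset([data.cell_ids[i] for i in train_idx])

    accs = []
    for value in grid:
        cfgs[stage] = replace(cfgs[stage], **{parameter: value})
        model = train_hierarchical(train_m, train_ann, test_m, cfgs)
        records = predict_hierarchical(model, test_m)
        row = _accuracy_row(records, ann, annotations.vocabulary.cm_label)
        accs.append(row["type_accuracy"])

    selected = select_elbow(grid, accs, tolerance)
    table = pd.DataFrame({"value": grid, "accuracy": accs})
    return table, selected


def select_elbow(grid: list[int], accuracies: list[float], tolerance: float = 0.005) -> int:
    """Smallest grid value whose gain to the next value is within ``tolerance``."""
    for i in range(len(grid) - 1):
        if accuracies[i + 1] - accuracies[i] <= tolerance + 1e-9:
            return grid[i]
    return grid[-1]
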