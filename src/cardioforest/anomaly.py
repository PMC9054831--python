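"""Class-probability anomaly detection with rejection thresholds.

A trained type classifier assigns every query cell a class and a class
probability. Cells of types the model never saw tend to receive low
probabilities for whichever class they fall into, so they can be rejected by
a per-class threshold. Thresholds are calibrated on two independent
development datasets: for each class, take the 5% quantile of the predicted-
class probabilities of cells annotated (by the model) as that class in each
development set, and use the minimum of the two. A prediction is an anomaly
when its probability is strictly below its class threshold.

"Cells in the corresponding class" is read as cells whose *predicted* class
matches — calibration then needs no ground-truth labels on the development
sets; a truth-conditioned variant is available via ``conditioning="truth"``
when labels exist.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CountMatrix, PredictionRecord
from .errors import CardioforestError

__all__ = ["AnomalyThresholds", "calibrate_thresholds", "apply_anomaly_filter"]


@dataclass
class AnomalyThresholds:
    """Per-class rejection thresholds with their calibration provenance."""

    thresholds: dict[str, float]
    quantile: float = 0.05
    provenance: tuple[str, str] = ("dev1", "dev2")
    dev_quantiles: pd.DataFrame | None = None  # class x (q_dev1, q_dev2)

    def __post_init__(self) -> None:
        for cls, t in self.thresholds.items():
            if not (0.0 <= t <= 1.0):
                raise ValueError(f"threshold for {cls!r} outside [0, 1]: {t}")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"threshold": pd.Series(self.thresholds)}
        ).rename_axis("class")
        if self.dev_quantiles is not None:
            df = df.join(self.dev_quantiles)
        return df


def _dev_class_probabilities(
    model,  # transfer.HierarchicalClassifier
    dev: CountMatrix,
    labels: pd.Series | None,
    conditioning: str,
) -> dict[str, np.ndarray]:
    """Per-class arrays of predicted-class probabilities on one dev set."""
    from .transfer import _ensure_lognorm, _stage_test_scaled, predict_stage

    _ensure_lognorm(dev)
    scaled = _stage_test_scaled(model.type_stage, dev)
    predicted, proba = predict_stage(model.type_stage, scaled, model.type_stage.selected_genes)
    p_of_pred = proba.to_numpy().max(axis=1)
    if conditioning == "predicted":
        keys = predicted
    elif conditioning == "truth":
        if labels is None:
            raise CardioforestError("truth conditioning requires dev-set labels")
        keys = np.asarray(labels.loc[dev.cell_ids]).astype(str)
    else:
        raise CardioforestError(f"unknown conditioning {conditioning!r}")
    out: dict[str, np.ndarray] = {}
    for cls in np.unique(keys):
        out[str(cls)] = p_of_pred[keys == cls]
    return out


def calibrate_thresholds(
    model,  # transfer.HierarchicalClassifier
    dev_sets: list[tuple[CountMatrix, pd.Series | None]],
    quantile: float = 0.05,
    conditioning: str = "predicted",
    names: tuple[str, str] = ("dev1", "dev2"),
) -> AnomalyThresholds:
    """Calibrate per-class thresholds from exactly two development datasets.

    Each dev set is predicted with the model (per-dataset scaling as always);
    for every type class the ``quantile`` (default 5%) of its predicted-class
    probabilities is taken per dev set and the minimum of the two becomes the
    threshold. A class absent from one dev set contributes nothing from that
    set; absent from both it gets threshold 0 with a warning.
    """
    if len(dev_sets) != 2:
        raise CardioforestError("calibration requires exactly two development sets")
    per_set: list[dict[str, float]] = []
    for dev, labels in dev_sets:
        probs = _dev_class_probabilities(model, dev, labels, conditioning)
        per_set.append({cls: float(np.quantile(v, quantile)) for cls, v in probs.items()})

    thresholds: dict[str, float] = {}
    rows = {}
    for cls in model.type_stage.class_labels:
        qs = [s[cls] for s in per_set if cls in s]
        if not qs:
            warnings.warn(f"class {cls!r} absent from both development sets; threshold 0")
            thresholds[cls] = 0.0
        else:
            if len(qs) == 1:
                warnings.warn(f"class {cls!r} present in only one development set")
            thresholds[cls] = min(qs)
        rows[cls] = {
            f"q_{names[0]}": per_set[0].get(cls, np.nan),
            f"q_{names[1]}": per_set[1].get(cls, np.nan),
        }
    return AnomalyThresholds(
        thresholds=thresholds,
        quantile=quantile,
        provenance=names,
        dev_quantiles=pd.DataFrame.from_dict(rows, orient="index").rename_axis("class"),
    )


def apply_anomaly_filter(
    records: list[PredictionRecord], thresholds: AnomalyThresholds
) -> tuple[list[PredictionRecord], list[PredictionRecord]]:
    """Set ``is_anomaly`` on each record and return (all records, kept view).

    A cell is an anomaly when its type probability is *strictly below* the
    threshold of its predicted class (a probability equal to the threshold is
    kept). Anomalous cells lose their zone/side labels. Raising any threshold
    can only flag more cells, never fewer.
    """
    kept = []
    for r in records:
        if r.predicted_type not in thresholds.thresholds:
            raise CardioforestError(f"no threshold for class {r.predicted_type!r}")
        r.is_anomaly = r.type_probability < thresholds.thresholds[r.predicted_type]
        if r.is_anomaly:
            r.predicted_zone = None
            r.zone_probability = None
            r.predicted_side = None
            r.side_probability = None
        else:
            kept.append(r)
    return records, kept
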