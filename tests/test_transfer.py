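"""Feature selection, scaling, quantile normalization and the forest stack."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import cardioforest as cf
from cardioforest.errors import CardioforestError, ConfigError
from cardioforest.simulate import CellTypeSpec, PlatformShift, SubgroupSpec
from cardioforest.transfer import (
    _scale_values,
    _stratified_folds,
    predict_stage,
    quantile_map,
    select_elbow,
)

from conftest import make_matrix


# -- scaling ----------------------------------------------------------------


def test_scale_constant_gene_is_all_zero():
    scaled, rec = _scale_values(np.full((1, 6), 2.0), ["g"])
    np.testing.assert_array_equal(scaled, 0.0)
    assert rec.q95[0] == 0.0


def test_scale_1_to_20_hand_computation():
    vals = np.arange(1.0, 21.0)[None, :]
    scaled, rec = _scale_values(vals, ["g"])
    assert rec.minimum[0] == 1.0
    # q95 of 0..19 with linear interpolation: h = 19*0.95 = 18.05
    assert rec.q95[0] == pytest.approx(18.05)
    assert scaled[0].max() == pytest.approx(19 / 18.05)


def test_scaled_min_zero_q95_one():
    rng = np.random.default_rng(0)
    vals = rng.gamma(2.0, 1.0, size=(10, 40))
    scaled, _ = _scale_values(vals, [f"g{i}" for i in range(10)])
    np.testing.assert_allclose(scaled.min(axis=1), 0.0, atol=1e-12)
    np.testing.assert_allclose(np.quantile(scaled, 0.95, axis=1), 1.0, atol=1e-12)


def test_scale_invariant_to_additive_shift():
    rng = np.random.default_rng(1)
    vals = rng.normal(size=(5, 30))
    a, _ = _scale_values(vals, list("abcde"))
    b, _ = _scale_values(vals + 7.5, list("abcde"))
    np.testing.assert_allclose(a, b, atol=1e-12)


def test_scale_matrix_uses_requested_genes(toy_matrix):
    cf.log_normalize(toy_matrix)
    scaled, rec = cf.scale_matrix(toy_matrix, ["g2", "g0"])
    assert rec.genes == ["g2", "g0"]
    assert scaled.shape == (2, 2)


# -- quantile normalization -------------------------------------------------


def test_quantile_normalize_sorted_profiles_identical():
    rng = np.random.default_rng(2)
    mats = [rng.normal(size=(20, 7)), rng.normal(size=(20, 5))]
    out, ref = cf.quantile_normalize(mats)
    for m in out:
        for c in range(m.shape[1]):
            np.testing.assert_allclose(np.sort(m[:, c]), ref)


def test_quantile_normalize_fixed_point_for_shared_profile():
    # every cell is a permutation of the same values -> already normalized
    base = np.array([0.0, 1.0, 2.0, 5.0])
    cols = [np.random.default_rng(i).permutation(base) for i in range(6)]
    mat = np.stack(cols, axis=1)
    out, _ = cf.quantile_normalize([mat[:, :3], mat[:, 3:]])
    np.testing.assert_allclose(np.concatenate(out, axis=1), mat)


def test_quantile_normalize_three_cell_oracle():
    mat = np.array([[1.0, 6.0, 2.0], [3.0, 4.0, 0.0], [5.0, 2.0, 9.0]])
    # independent oracle: mean of sorted columns, re-assigned by rank
    sorted_cols = np.sort(mat, axis=0)
    ref = sorted_cols.mean(axis=1)
    expected = np.empty_like(mat)
    for c in range(3):
        ranks = np.argsort(np.argsort(mat[:, c]))
        expected[:, c] = ref[ranks]
    (out,), _ = cf.quantile_normalize([mat])
    np.testing.assert_allclose(out, expected)


def test_quantile_normalize_shape_mismatch():
    with pytest.raises(CardioforestError, match="mismatch"):
        cf.quantile_normalize([np.zeros((3, 2)), np.zeros((4, 2))])


# -- feature selection ------------------------------------------------------


def lognorm_matrix(vals, counts=None):
    vals = np.asarray(vals, dtype=float)
    counts = (vals > 0).astype(int) if counts is None else counts
    m = make_matrix(counts)
    m.layers["lognorm"] = vals
    return m


def test_detection_filter_quarter_of_cells():
    rng = np.random.default_rng(3)
    vals = rng.gamma(2, 1, size=(30, 16)) + 0.1
    vals[0, 3:] = 0.0  # gene 0 detected in 3 of 16 cells < 1/4
    m1 = lognorm_matrix(vals)
    m2 = lognorm_matrix(vals.copy())
    genes = cf.select_features(m1, m2)
    assert "g0" not in genes


def test_top_half_keeps_exactly_fifty_of_hundred():
    rng = np.random.default_rng(4)
    vals = rng.gamma(2, 1, size=(100, 40)) + 0.1
    m1 = lognorm_matrix(vals)
    m2 = lognorm_matrix(vals.copy())
    genes = cf.select_features(m1, m2)
    assert len(genes) == 50


def test_selected_set_matches_brute_force_oracle():
    rng = np.random.default_rng(5)
    vals = rng.gamma(2, 1, size=(20, 30)) + 0.1
    m1 = lognorm_matrix(vals)
    m2 = lognorm_matrix(vals.copy())
    genes = set(cf.select_features(m1, m2))

    # oracle: CV2 per gene, robust 1/mean trend, keep top half by ratio
    mean = vals.mean(axis=1)
    cv2 = vals.var(axis=1, ddof=1) / mean**2
    fit = sm.RLM(cv2, sm.add_constant(1.0 / mean), M=sm.robust.norms.HuberT()).fit()
    ratio = cv2 / np.maximum(fit.fittedvalues, 1e-12)
    expected = {f"g{i}" for i in np.argsort(-ratio)[:10]}
    assert genes == expected


def test_empty_intersection_raises():
    vals = np.zeros((8, 16))
    vals[:, :3] = 1.0  # detected in 3/16 < 1/4 everywhere
    m1 = lognorm_matrix(vals)
    m2 = lognorm_matrix(vals.copy())
    with pytest.raises(CardioforestError, match="relax"):
        cf.select_features(m1, m2)


# -- stage training / prediction --------------------------------------------


def separable_toy(seed=0, n_per_class=200, n_genes=30, n_markers=10):
    rng = np.random.default_rng(seed)
    scaled = rng.uniform(0, 0.2, size=(n_genes, 2 * n_per_class))
    scaled[:n_markers, :n_per_class] += 0.8  # class A markers
    scaled[n_markers : 2 * n_markers, n_per_class:] += 0.8  # class B markers
    labels = np.array(["A"] * n_per_class + ["B"] * n_per_class)
    genes = [f"g{i:02d}" for i in range(n_genes)]
    return scaled, genes, labels


def test_separable_toy_perfect_training_accuracy():
    scaled, genes, labels = separable_toy()
    cfg = cf.StageConfig("type", n_trees=50, n_top_genes=20, seed=0)
    stage = cf.train_stage(scaled, genes, labels, cfg)
    pred, proba = predict_stage(stage, scaled, genes)
    assert (pred == labels).all()
    np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)


def test_top_importance_genes_are_true_markers():
    scaled, genes, labels = separable_toy(seed=1)
    cfg = cf.StageConfig("type", n_trees=100, n_top_genes=20, seed=1)
    stage = cf.train_stage(scaled, genes, labels, cfg)
    true_markers = set(genes[:20])
    hit = len(set(stage.feature_genes) & true_markers) / len(stage.feature_genes)
    assert hit >= 0.8


def test_single_cell_class_rejected():
    scaled, genes, labels = separable_toy(n_per_class=5)
    labels[0] = "C"
    with pytest.raises(CardioforestError, match="'C'"):
        cf.train_stage(scaled, genes, labels, cf.StageConfig("type", 10, 5))


def test_predict_uniform_probability_tie_breaks_alphabetically():
    class UniformForest:
        classes_ = np.array(["a", "b", "c"])

        def predict_proba(self, X):
            return np.full((len(X), 3), 1 / 3)

    stage = cf.TrainedStage(
        stage="type",
        selected_genes=["g1"],
        feature_genes=["g1"],
        forest=UniformForest(),
        class_labels=["a", "b", "c"],
        seed=0,
    )
    labels, _ = predict_stage(stage, np.zeros((1, 4)), ["g1"])
    assert (labels == "a").all()


def test_predict_missing_feature_genes_errors():
    scaled, genes, labels = separable_toy()
    stage = cf.train_stage(scaled, genes, labels, cf.StageConfig("type", 20, 10))
    with pytest.raises(CardioforestError, match="missing feature genes"):
        predict_stage(stage, scaled[:5], genes[:5])


def test_training_is_deterministic():
    scaled, genes, labels = separable_toy(seed=2)
    cfg = cf.StageConfig("type", n_trees=30, n_top_genes=10, seed=7)
    s1 = cf.train_stage(scaled, genes, labels, cfg)
    s2 = cf.train_stage(scaled, genes, labels, cfg)
    assert s1.feature_genes == s2.feature_genes
    p1, _ = predict_stage(s1, scaled, genes)
    p2, _ = predict_stage(s2, scaled, genes)
    assert (p1 == p2).all()


# -- hierarchy --------------------------------------------------------------


def small_sim(seed=0):
    cfg = cf.SimulationConfig(
        seed=seed,
        n_genes=400,
        cell_type_spec={
            "cm": CellTypeSpec(80, 25, 8.0),
            "f": CellTypeSpec(80, 25, 8.0),
            "ep": CellTypeSpec(80, 25, 8.0),
        },
        zone_spec=SubgroupSpec(n_markers=16, fold_change=3.0),
        side_spec=SubgroupSpec(n_markers=12, fold_change=1.8),
    )
    return cfg


def small_cfgs(seed=0):
    return {
        "type": cf.StageConfig("type", n_trees=60, n_top_genes=60, seed=seed),
        "zone": cf.StageConfig("zone", n_trees=60, n_top_genes=30, seed=seed),
        "side": cf.StageConfig("side", n_trees=60, n_top_genes=30, quantile_normalize=True, seed=seed),
    }


def test_default_stage_hyperparameters():
    cfgs = cf.default_stage_configs()
    assert (cfgs["type"].n_trees, cfgs["type"].n_top_genes) == (300, 500)
    assert (cfgs["zone"].n_trees, cfgs["zone"].n_top_genes) == (300, 100)
    assert (cfgs["side"].n_trees, cfgs["side"].n_top_genes) == (500, 100)
    assert cfgs["side"].quantile_normalize and not cfgs["type"].quantile_normalize


def test_hierarchy_containment_and_record_count():
    cfg = small_sim(3)
    ref, ann = cf.simulate_reference(cfg)
    qry, _ = cf.simulate_query(cfg)
    cf.log_normalize(ref)
    cf.log_normalize(qry)
    model = cf.train_hierarchical(ref, ann, qry, small_cfgs(3))
    records = cf.predict_hierarchical(model, qry)
    assert len(records) == qry.n_cells
    for r in records:
        if r.predicted_type == "cm":
            assert r.predicted_zone in {"A", "V"} and r.predicted_side in {"L", "R"}
        else:
            assert r.predicted_zone is None and r.predicted_side is None


def test_missing_side_labels_skip_side_stage():
    cfg = small_sim(4)
    ref, ann = cf.simulate_reference(cfg)
    qry, _ = cf.simulate_query(cfg)
    cf.log_normalize(ref)
    cf.log_normalize(qry)
    ann.df["side"] = pd.NA
    with pytest.warns(UserWarning, match="side"):
        model = cf.train_hierarchical(ref, ann, qry, small_cfgs(4))
    assert model.side_stage is None
    records = cf.predict_hierarchical(model, qry)
    assert all(r.predicted_side is None for r in records)


# -- cross-validation and tuning --------------------------------------------


def test_stratified_folds_partition_cells():
    labels = np.array(["a"] * 12 + ["b"] * 9)
    folds = _stratified_folds(labels, 3, seed=0)
    assert sorted(np.unique(folds)) == [0, 1, 2]
    assert len(folds) == 21
    for cls, total in (("a", 12), ("b", 9)):
        sizes = [((labels == cls) & (folds == f)).sum() for f in range(3)]
        assert sum(sizes) == total and max(sizes) - min(sizes) <= 1


def test_two_folds_of_ten_cells_split_five_five():
    labels = np.array(["a"] * 10)
    folds = _stratified_folds(labels, 2, seed=1)
    assert sorted(np.bincount(folds)) == [5, 5]


def test_cross_validation_pooled_accuracy_on_separable_data():
    cfg = small_sim(7)
    ref, ann = cf.simulate_reference(cfg)
    cf.log_normalize(ref)
    table = cf.cross_validate(ref, ann, k=3, cfgs=small_cfgs(7), seed=7)
    pooled = table[table["fold"] == "pooled"].iloc[0]
    assert pooled["n_cells"] == ref.n_cells
    assert pooled["type_accuracy"] >= 0.98


def test_cross_validation_k_validation():
    cfg = small_sim(8)
    ref, ann = cf.simulate_reference(cfg)
    with pytest.raises(ConfigError):
        cf.cross_validate(ref, ann, k=ref.n_cells + 1)
    with pytest.raises(ConfigError):
        cf.cross_validate(ref, ann, k=1)


@pytest.mark.parametrize(
    "accs, expected",
    [
        ([0.70, 0.90, 0.905, 0.906], 100),  # flattening after 100
        ([0.80, 0.80, 0.80, 0.80], 50),  # monotone flat -> smallest
        ([0.50, 0.60, 0.70, 0.80], 400),  # keeps climbing -> largest
    ],
)
def test_elbow_rule(accs, expected):
    assert select_elbow([50, 100, 200, 400], accs, tolerance=0.005) == expected


def test_tune_grid_validation():
    cfg = small_sim(9)
    ref, ann = cf.simulate_reference(cfg)
    with pytest.raises(ConfigError):
        cf.tune_hyperparameter(ref, ann, "n_trees", [100])
    with pytest.raises(ConfigError):
        cf.tune_hyperparameter(ref, ann, "n_trees", [200, 100])


def test_tune_sweep_returns_table_and_selection():
    cfg = small_sim(10)
    ref, ann = cf.simulate_reference(cfg)
    cf.log_normalize(ref)
    table, selected = cf.tune_hyperparameter(
        ref, ann, "n_trees", [20, 40], cfgs=small_cfgs(10), seed=10
    )
    assert list(table["value"]) == [20, 40]
    assert selected in (20, 40)
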