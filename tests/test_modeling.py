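import numpy as np
import pandas as pd
import pytest

import pcorona as pc
from pcorona.modeling import _derived_seed


def test_metric_oracles():
    rng = np.random.default_rng(0)
    true = rng.normal(size=200)
    pred = true + rng.normal(scale=0.5, size=200)
    r = float(np.corrcoef(true, pred)[0, 1])
    assert pc.r_squared(true, pred) == pytest.approx(r * r, abs=1e-12)
    assert pc.rmse(true, pred) == pytest.approx(
        float(np.sqrt(np.mean((true - pred) ** 2))), abs=1e-12
    )
    assert pc.rmse(np.zeros(2), np.array([3.0, 4.0])) == pytest.approx(np.sqrt(12.5))
    # squared Pearson is invariant to affine rescaling of predictions
    assert pc.r_squared(true, 2.0 * pred + 5.0) == pytest.approx(
        pc.r_squared(true, pred), abs=1e-12
    )
    # literal reading: signed, and the square of its magnitude relation holds
    lit = pc.r_squared(true, pred, literal=True)
    assert lit > 0


def test_metric_errors():
    with pytest.raises(pc.DimensionError):
        pc.r_squared(np.ones(3), np.ones(4))
    with pytest.raises(pc.DegenerateInputError):
        pc.r_squared(np.full(5, 2.0), np.arange(5.0))
    with pytest.raises(pc.DimensionError):
        pc.rmse(np.array([]), np.array([]))


def test_train_rf_determinism_and_inputs():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(60, 4))
    y = X[:, 0] * 2 + rng.normal(scale=0.1, size=60)
    cfg = pc.ModelConfig(n_trees=20, seed=5)
    a = pc.train_rf(X, y, cfg)
    b = pc.train_rf(X, y, cfg)
    np.testing.assert_array_equal(a.predict(X), b.predict(X))
    with pytest.raises(pc.TrainingError):
        pc.train_rf(X[:5], y[:5], cfg)
    with pytest.raises(pc.ConfigError):
        pc.train_rf(X, None, cfg)


def test_derived_seeds_in_range():
    for base in (0, 1, 123456789, 2**31 - 1, 2**33):
        for salts in ((0,), (59, 3), (59, 3, 7)):
            s = _derived_seed(base, *salts)
            assert 0 <= s < 2**31
    assert _derived_seed(1, 2) != _derived_seed(1, 3)
    assert _derived_seed(1, 2, 3) != _derived_seed(1, 3, 2)


def test_aggregate_importance_sums_to_one():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(80, 5))
    y = X[:, 0] + rng.normal(scale=0.1, size=80)
    names = ["f=a", "f=b", "g", "h", "i"]
    parent = {"f=a": "f", "f=b": "f", "g": "g", "h": "h", "i": "i"}
    fm = pc.train_rf(X, y, pc.ModelConfig(n_trees=20, seed=0))
    fm.encoded_names, fm.parent_of = names, parent
    agg = pc.aggregate_importance(fm)
    assert set(agg) == {"f", "g", "h", "i"}
    assert sum(agg.values()) == pytest.approx(1.0)


def test_feature_importance_filter_and_sort():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(100, 3))
    y = 3 * X[:, 0] + 0.5 * X[:, 1] + rng.normal(scale=0.05, size=100)
    models = []
    for s in range(3):
        fm = pc.train_rf(X, y, pc.ModelConfig(n_trees=30, seed=s))
        fm.encoded_names = ["a", "b", "c"]
        fm.parent_of = {"a": "a", "b": "b", "c": "c"}
        models.append(fm)
    imp = pc.feature_importance(models, threshold=0.01)
    keys = list(imp)
    assert keys[0] == "a"
    assert list(imp.values()) == sorted(imp.values(), reverse=True)
    assert all(v > 0.01 for v in imp.values())
    assert pc.filter_importances({"x": 0.5, "y": 0.001}) == {"x": 0.5}


def test_learning_curve_monotone_tendency(synth_small):
    dataset, _ = synth_small
    enc = pc.CoronaEncoder().fit_transform(dataset)
    y = dataset.rpa.iloc[:, 0].to_numpy()
    cfg = pc.ModelConfig(n_trees=30, cv_folds=5, seed=0)
    curve = pc.learning_curve(enc.X, y, cfg, sizes=[40, 160])
    assert [s for s, _, _ in curve] == [40, 160]
    # more data should not substantially hurt CV error
    assert curve[-1][1] <= curve[0][1] * 1.1


def test_run_ablation_structure(synth_small):
    dataset, _ = synth_small
    cfg = pc.ModelConfig(n_trees=15, seed=0)
    reports, models = pc.run_ablation(
        dataset, strategies=("none", "random_over"), config=cfg, return_models=True
    )
    assert [r.strategy for r in reports] == ["none", "random_over"]
    for r in reports:
        assert set(r.per_protein) == set(dataset.protein_ids)
        assert r.audit_passed
        assert np.isfinite(r.mean_rmse)
        assert abs(sum(r.importances.values()) - 1.0) < 1e-6
    frame = pc.summary_frame(reports)
    assert list(frame.columns) == ["strategy", "mean_r2", "mean_rmse"]
    long = pc.per_protein_frame(reports)
    assert len(long) == 2 * len(dataset.protein_ids)

    # models usable for new-row prediction through their stored encoders
    preds = pc.predict_new(models["none"], dataset.factors.iloc[:3])
    assert preds.shape == (3, len(dataset.protein_ids))
    assert np.all(preds > 0)


def test_run_ablation_deterministic(synth_small):
    dataset, _ = synth_small
    cfg = pc.ModelConfig(n_trees=10, seed=2)
    a = pc.summary_frame(pc.run_ablation(dataset, strategies=("none", "wercs"), config=cfg))
    b = pc.summary_frame(pc.run_ablation(dataset, strategies=("none", "wercs"), config=cfg))
    pd.testing.assert_frame_equal(a, b)


def test_model_config_validation():
    with pytest.raises(pc.ConfigError):
        pc.ModelConfig(n_trees=0)
    with pytest.raises(pc.ConfigError):
        pc.ModelConfig(cv_folds=1)
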