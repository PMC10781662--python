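import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import pcorona as pc


def test_min_max_basic():
    out, params = pc.min_max_normalize(np.array([2.0, 4.0, 6.0]))
    np.testing.assert_allclose(out, [0.0, 0.5, 1.0])
    assert params == (2.0, 6.0)


def test_min_max_param_reuse_no_clipping(caplog):
    _, params = pc.min_max_normalize(np.array([0.0, 10.0]))
    with caplog.at_level(logging.WARNING, logger="pcorona.preprocessing"):
        out, _ = pc.min_max_normalize(np.array([-5.0, 15.0]), params)
    np.testing.assert_allclose(out, [-0.5, 1.5])  # out-of-range kept, not clipped
    assert any("outside the training range" in r.getMessage() for r in caplog.records)


def test_min_max_constant_column_warns(caplog):
    with caplog.at_level(logging.WARNING, logger="pcorona.preprocessing"):
        out, params = pc.min_max_normalize(np.full(4, 7.0))
    np.testing.assert_array_equal(out, np.zeros(4))
    assert params == (7.0, 7.0)
    assert any("constant" in r.getMessage() for r in caplog.records)


@given(
    st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=50).filter(
        lambda v: max(v) > min(v)
    )
)
def test_min_max_range_property(values):
    out, _ = pc.min_max_normalize(np.array(values))
    assert out.min() >= 0.0 and out.max() <= 1.0
    assert out.min() == pytest.approx(0.0) and out.max() == pytest.approx(1.0)


def test_one_hot_full_encoding(toy_dataset):
    enc = pc.one_hot_encode(toy_dataset)
    # full (non-dropped) encoding: one column per observed (factor, level)
    assert enc.encoded_names == [
        "np_type=metal", "np_type=polymer", "np_type=silica",
        "medium=PBS", "medium=water",
    ]
    assert enc.X.shape == (4, 5)
    row_sums = enc.X.reshape(4, -1)[:, :3].sum(axis=1)
    np.testing.assert_array_equal(row_sums, np.ones(4))
    assert enc.parent_of["np_type=metal"] == "np_type"


def test_encoder_round_trip_and_unseen_level(toy_dataset, caplog):
    enc = pc.CoronaEncoder().fit(toy_dataset)
    mat = enc.transform(toy_dataset.factors)
    assert mat.X.shape == (4, 5 + 2)
    assert mat.encoded_names[-2:] == ["size_nm", "zeta_mv"]
    np.testing.assert_allclose(mat.X[:, -2], (toy_dataset.factors["size_nm"] - 50) / 150)

    new = toy_dataset.factors.iloc[:1].copy()
    new.loc[0, "np_type"] = "unobtainium"
    with caplog.at_level(logging.WARNING, logger="pcorona.preprocessing"):
        mat2 = enc.transform(new)
    np.testing.assert_array_equal(mat2.X[0, :3], np.zeros(3))  # all-zero group
    assert any("unseen level" in r.getMessage() for r in caplog.records)


def test_encoder_missing_column_raises(toy_dataset):
    enc = pc.CoronaEncoder().fit(toy_dataset)
    with pytest.raises(pc.DimensionError, match="zeta_mv"):
        enc.transform(toy_dataset.factors.drop(columns=["zeta_mv"]))
    with pytest.raises(pc.ConfigError, match="not fitted"):
        pc.CoronaEncoder().transform(toy_dataset.factors)


def test_feature_groups(toy_dataset):
    mat = pc.CoronaEncoder().fit_transform(toy_dataset)
    groups = mat.feature_groups()
    kinds = {name: kind for name, kind, _ in groups}
    assert kinds == {"np_type": "onehot", "medium": "onehot",
                     "size_nm": "numeric", "zeta_mv": "numeric"}
    cols = {name: c for name, _, c in groups}
    assert cols["np_type"] == [0, 1, 2]
    assert cols["size_nm"] == [5]


def test_stratified_split_ratio_and_distribution(skewed_targets):
    split = pc.stratified_split(skewed_targets, ratio=0.1, n_strata=10, seed=0)
    n = skewed_targets.size
    assert split.test.size == pytest.approx(0.1 * n, abs=10)
    assert split.train.size + split.test.size == n
    assert np.intersect1d(split.train, split.test).size == 0
    # quantile stratification: test medians track the full-sample median
    assert np.median(skewed_targets[split.test]) == pytest.approx(
        np.median(skewed_targets), rel=0.35
    )
    # roughly ratio per decile
    deciles = np.quantile(skewed_targets, np.linspace(0, 1, 11))
    below_med_test = np.sum(skewed_targets[split.test] <= deciles[5])
    assert 0.3 <= below_med_test / split.test.size <= 0.7


def test_stratified_split_determinism(skewed_targets):
    a = pc.stratified_split(skewed_targets, seed=5)
    b = pc.stratified_split(skewed_targets, seed=5)
    c = pc.stratified_split(skewed_targets, seed=6)
    np.testing.assert_array_equal(a.test, b.test)
    assert not np.array_equal(a.test, c.test)


def test_stratified_split_bad_ratio(skewed_targets):
    with pytest.raises(pc.ConfigError):
        pc.stratified_split(skewed_targets, ratio=0.0)
    with pytest.raises(pc.ConfigError):
        pc.stratified_split(skewed_targets, ratio=1.0)


def test_split_overlap_guard():
    with pytest.raises(pc.ConfigError, match="overlap"):
        pc.SplitIndices(train=np.array([0, 1]), test=np.array([1, 2]), n_strata=2)
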