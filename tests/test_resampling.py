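import numpy as np
import pytest

import pcorona as pc


@pytest.fixture
def rel(skewed_targets):
    return pc.pchip_fit(pc.default_control_points(skewed_targets))


@pytest.fixture
def xy(skewed_targets):
    rng = np.random.default_rng(1)
    X = rng.normal(size=(skewed_targets.size, 6))
    return X, skewed_targets


def test_random_oversample_counts_and_provenance(xy, rel):
    X, y = xy
    params = pc.ResampleParams(threshold=0.8, over_percent=2.0, seed=0)
    out = pc.random_oversample(X, y, rel, params)
    phi = rel(y)
    n_rare = int(np.sum(phi >= 0.8))
    assert n_rare > 0
    assert out.n_rows == y.size + round(2.0 * n_rare)
    # originals preserved verbatim at the front
    np.testing.assert_array_equal(out.X[: y.size], X)
    np.testing.assert_array_equal(out.y[: y.size], y)
    for tag in out.provenance[y.size:]:
        kind, src = tag
        assert kind == "replica"
        assert phi[src] >= 0.8
        # replica rows are exact copies of their source
        i = out.provenance.index(tag)
        np.testing.assert_array_equal(out.X[i], X[src])


def test_random_oversample_empty_rare_region(xy):
    X, y = xy
    flat = pc.pchip_fit([pc.ControlPoint(y.min(), 0.0), pc.ControlPoint(y.max() + 1e9, 1.0)])
    out = pc.random_oversample(X, y, flat)
    assert out.n_rows == y.size


def test_smoter_synthetic_rows(xy, rel):
    X, y = xy
    groups = [("block", "onehot", [0, 1]), ("rest", "numeric", [2, 3, 4, 5])]
    # make the one-hot block actually binary
    X = X.copy()
    X[:, 0] = (y > np.median(y)).astype(float)
    X[:, 1] = 1.0 - X[:, 0]
    params = pc.ResampleParams(threshold=0.8, over_percent=2.0, k_neighbors=5, seed=0)
    out = pc.smoter(X, y, rel, params, feature_kinds=groups)
    phi = rel(y)
    rare = np.flatnonzero(phi >= 0.8)
    n_new = round(2.0 * rare.size)
    assert out.n_rows == y.size + n_new
    rare_set = set(rare.tolist())
    for i, tag in enumerate(out.provenance[y.size:], start=y.size):
        kind, i_seed, i_nb = tag
        assert kind == "synthetic"
        assert i_seed in rare_set and i_nb in rare_set and i_seed != i_nb
        row = out.X[i]
        # numeric features between the two parents
        for c in (2, 3, 4, 5):
            lo = min(X[i_seed, c], X[i_nb, c])
            hi = max(X[i_seed, c], X[i_nb, c])
            assert lo - 1e-12 <= row[c] <= hi + 1e-12
        # one-hot group copied wholesale from one parent
        assert (np.array_equal(row[:2], X[i_seed, :2])
                or np.array_equal(row[:2], X[i_nb, :2]))
        # target between the two parents' targets
        lo, hi = sorted((y[i_seed], y[i_nb]))
        assert lo - 1e-12 <= out.y[i] <= hi + 1e-12


def test_smoter_fallback_single_rare_row():
    rng = np.random.default_rng(0)
    y = np.concatenate([rng.uniform(0, 1, 30), [100.0]])
    X = rng.normal(size=(31, 3))
    rel = pc.pchip_fit(pc.default_control_points(y))
    out = pc.smoter(X, y, rel, pc.ResampleParams(seed=1))
    assert out.strategy == "smoter"
    assert all(tag[0] in ("original", "replica") for tag in out.provenance)


def test_smoter_reduces_k_for_tiny_rare_partition():
    rng = np.random.default_rng(2)
    y = np.concatenate([rng.uniform(0, 1, 40), [50.0, 60.0, 70.0]])
    X = rng.normal(size=(43, 3))
    rel = pc.pchip_fit(pc.default_control_points(y))
    out = pc.smoter(X, y, rel, pc.ResampleParams(k_neighbors=5, seed=1))
    assert out.n_rows > y.size  # still synthesized despite |Dr| <= k


def test_wercs_counts(xy, rel):
    X, y = xy
    n = y.size
    params = pc.ResampleParams(wercs_over_frac=0.5, wercs_under_frac=0.5, seed=3)
    out = pc.wercs(X, y, rel, params)
    import math

    n_over = math.ceil(0.5 * n)
    n_under = math.ceil(0.5 * n)
    assert out.n_rows == n - n_under + n_over
    kinds = [t[0] for t in out.provenance]
    assert kinds.count("replica") == n_over
    assert kinds.count("original") == n - n_under


def test_wercs_sampling_frequencies_track_relevance():
    """Replica draws with p ∝ Φ: frequency check within 3 standard errors."""
    X = np.zeros((2, 1))
    rel = pc.pchip_fit([pc.ControlPoint(0.0, 0.2, 0.0), pc.ControlPoint(0.5, 0.8, 0.0)])
    # constant extension puts the two targets at Φ = 0.2 and 0.8 exactly
    y = np.array([-1.0, 1.0])
    phi = np.array([0.2, 0.8])
    np.testing.assert_allclose(rel(y), phi)
    n_draws = 1000
    params = pc.ResampleParams(
        wercs_over_frac=n_draws / 2, wercs_under_frac=0.0, seed=9
    )
    out = pc.wercs(X, y, rel, params)
    picks = [t[1] for t in out.provenance if t[0] == "replica"]
    assert len(picks) == n_draws
    p1 = phi[1] / phi.sum()  # 0.8
    freq = np.mean(np.array(picks) == 1)
    se = np.sqrt(p1 * (1 - p1) / n_draws)
    assert abs(freq - p1) <= 3 * se


def test_wercs_never_empties_training_set():
    rng = np.random.default_rng(4)
    y = rng.lognormal(size=20)
    X = rng.normal(size=(20, 2))
    rel = pc.pchip_fit(pc.default_control_points(y))
    out = pc.wercs(X, y, rel, pc.ResampleParams(wercs_over_frac=0.0, wercs_under_frac=5.0))
    assert out.n_rows >= 1


def test_dispatcher_and_unknown_strategy(xy, rel):
    X, y = xy
    for s in pc.STRATEGIES:
        out = pc.resample(s, X, y, rel, pc.ResampleParams(seed=0))
        assert out.strategy == s
    with pytest.raises(pc.ConfigError, match="unknown strategy"):
        pc.resample("bogus", X, y, rel)


def test_resample_determinism(xy, rel):
    X, y = xy
    for s in pc.STRATEGIES:
        a = pc.resample(s, X, y, rel, pc.ResampleParams(seed=7))
        b = pc.resample(s, X, y, rel, pc.ResampleParams(seed=7))
        c = pc.resample(s, X, y, rel, pc.ResampleParams(seed=8))
        np.testing.assert_array_equal(a.y, b.y)
        np.testing.assert_array_equal(a.X, b.X)
        assert a.provenance == b.provenance
        assert not np.array_equal(a.y, c.y)


def test_indices_threading(xy, rel):
    X, y = xy
    idx = np.arange(1000, 1000 + y.size)
    out = pc.resample("random_over", X, y, rel, pc.ResampleParams(seed=0), indices=idx)
    assert out.origin_rows() <= set(idx.tolist())


def test_param_validation():
    with pytest.raises(pc.ConfigError):
        pc.ResampleParams(threshold=0.0)
    with pytest.raises(pc.ConfigError):
        pc.ResampleParams(k_neighbors=0)
    with pytest.raises(pc.ConfigError):
        pc.ResampleParams(over_percent=-1.0)


def test_distribution_diagnostics(skewed_targets, rel):
    rng = np.random.default_rng(5)
    X = rng.normal(size=(skewed_targets.size, 3))
    out = pc.resample("random_over", X, skewed_targets, rel, pc.ResampleParams(seed=0))
    var_b, var_a, ent_b, ent_a = pc.distribution_diagnostics(skewed_targets, out.y)
    assert var_b == pytest.approx(float(np.var(skewed_targets, ddof=1)))
    assert var_a > var_b  # oversampling the upper tail raises variance
    assert ent_a > ent_b  # ... and spreads histogram mass
    with pytest.raises(pc.ConfigError):
        pc.distribution_diagnostics(skewed_targets, np.array([]))
    with pytest.raises(pc.ConfigError):
        pc.distribution_diagnostics(skewed_targets, skewed_targets, n_bins=1)


def test_kde_overlay(skewed_targets, tmp_path):
    doubled = np.concatenate([skewed_targets, skewed_targets[skewed_targets > 2]])
    path = tmp_path / "kde.png"
    overlay = pc.kde_overlay(skewed_targets, doubled, path=path, title="demo")
    assert path.exists() and path.stat().st_size > 0
    assert overlay.grid.size == 512
    assert overlay.density_before.shape == overlay.grid.shape
    # resampled density has more mass in the tail
    tail = overlay.grid > 2
    assert overlay.density_after[tail].sum() > overlay.density_before[tail].sum()
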