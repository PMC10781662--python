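"""Relevance-guided resampling for imbalanced regression targets.

Three strategies rebalance a training set whose target is continuous
and skewed, steered by the relevance function Φ(y):

* **Random Oversampling** duplicates rows from the rare region
  (Φ(y) ≥ threshold) by seeded sampling with replacement.
* **SmoteR** synthesizes new rare rows by interpolating feature
  vectors between a rare seed row and one of its k nearest rare
  neighbours; one-hot groups are inherited atomically from one parent,
  and the synthetic target is the distance-weighted mean of the two
  parent targets.
* **WERCS** needs no threshold: it draws replicas with probability
  proportional to Φ(y) and removes rows with probability proportional
  to 1 − Φ(y).

Every output row carries provenance (original / replica / synthetic)
so that leakage audits can trace resampled rows back to source rows.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import gaussian_kde

from .exceptions import ConfigError, DimensionError
from .relevance import RelevanceFunction

logger = logging.getLogger(__name__)

STRATEGIES = ("random_over", "smoter", "wercs")


@dataclass(frozen=True)
class ResampleParams:
    """Strategy parameters.

    ``threshold`` is the relevance cutoff defining the rare partition
    (unused by WERCS); ``over_percent`` the number of new rows added
    per rare row; ``wercs_over_frac`` / ``wercs_under_frac`` the WERCS
    replication / removal fractions of the training size.
    """

    threshold: float = 0.8
    over_percent: float = 2.0
    k_neighbors: int = 5
    wercs_over_frac: float = 0.5
    wercs_under_frac: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ConfigError(f"threshold must be in (0, 1), got {self.threshold}")
        if self.k_neighbors < 1:
            raise ConfigError("k_neighbors must be >= 1")
        if min(self.over_percent, self.wercs_over_frac, self.wercs_under_frac) < 0:
            raise ConfigError("resampling fractions must be non-negative")


@dataclass
class ResampledTrainSet:
    """A training set after one resampling strategy.

    ``provenance`` tags each row: ``("original", i)``,
    ``("replica", i)`` or ``("synthetic", i_seed, i_neighbor)``, with
    indices referring to the caller's row indexing (``indices``
    argument, defaulting to positions).
    """

    X: np.ndarray
    y: np.ndarray
    provenance: list[tuple]
    strategy: str
    params: ResampleParams

    @property
    def n_rows(self) -> int:
        return self.y.size

    def origin_rows(self) -> set[int]:
        """Every source-row index any output row derives from."""
        out: set[int] = set()
        for tag in self.provenance:
            out.update(tag[1:])
        return out


def _as_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise DimensionError(f"X has shape {X.shape} but y has {y.size} rows")
    return X, y


def _indices(y: np.ndarray, indices: np.ndarray | None) -> np.ndarray:
    if indices is None:
        return np.arange(y.size)
    indices = np.asarray(indices, dtype=int)
    if indices.size != y.size:
        raise DimensionError("indices must align with y")
    return indices


def random_oversample(
    X: np.ndarray,
    y: np.ndarray,
    relevance: RelevanceFunction,
    params: ResampleParams = ResampleParams(),
    indices: np.ndarray | None = None,
) -> ResampledTrainSet:
    """Duplicate rare-region rows (Φ(y) ≥ threshold) with replacement.

    Adds ``round(over_percent · |rare|)`` replicas; all original rows
    are retained.  An empty rare region returns the input unchanged
    with a warning.
    """
    X, y = _as_xy(X, y)
    idx = _indices(y, indices)
    phi = np.atleast_1d(relevance(y))
    rare = np.flatnonzero(phi >= params.threshold)
    prov: list[tuple] = [("original", int(i)) for i in idx]
    if rare.size == 0:
        logger.warning("random_oversample: no rows reach relevance %.2f; returning input", params.threshold)
        return ResampledTrainSet(X.copy(), y.copy(), prov, "random_over", params)
    n_new = int(round(params.over_percent * rare.size))
    rng = np.random.default_rng(params.seed)
    picks = rng.choice(rare, size=n_new, replace=True) if n_new else np.empty(0, dtype=int)
    X_out = np.vstack([X, X[picks]]) if n_new else X.copy()
    y_out = np.concatenate([y, y[picks]])
    prov += [("replica", int(idx[p])) for p in picks]
    return ResampledTrainSet(X_out, y_out, prov, "random_over", params)


def smoter(
    X: np.ndarray,
    y: np.ndarray,
    relevance: RelevanceFunction,
    params: ResampleParams = ResampleParams(),
    feature_kinds: list[tuple[str, str, list[int]]] | None = None,
    indices: np.ndarray | None = None,
) -> ResampledTrainSet:
    """Interpolate synthetic rows between rare seeds and rare neighbours.

    For each synthetic row a rare seed and one of its k nearest rare
    neighbours (Euclidean distance in the encoded space) are drawn;
    numeric features are placed at x_seed + u (x_neighbor − x_seed)
    with u ~ Uniform(0, 1), one-hot groups are copied wholesale from
    seed or neighbour by fair coin, and the target is the
    distance-weighted mean of the parents' targets (closer parent
    weighs more).  Falls back to random oversampling when fewer than
    two rare rows exist.
    """
    X, y = _as_xy(X, y)
    idx = _indices(y, indices)
    phi = np.atleast_1d(relevance(y))
    rare = np.flatnonzero(phi >= params.threshold)
    if rare.size < 2:
        logger.warning("smoter: rare partition has %d row(s); falling back to random oversampling", rare.size)
        out = random_oversample(X, y, relevance, params, indices=idx)
        return replace(out, strategy="smoter")
    k = params.k_neighbors
    if rare.size <= k:
        k = rare.size - 1
        logger.warning("smoter: rare partition smaller than k; reduced k to %d", k)

    if feature_kinds is None:
        feature_kinds = [("all", "numeric", list(range(X.shape[1])))]
    numeric_cols = [c for _, kind, cols in feature_kinds if kind == "numeric" for c in cols]
    onehot_groups = [cols for _, kind, cols in feature_kinds if kind == "onehot"]

    Xr = X[rare]
    dists = cdist(Xr, Xr)
    np.fill_diagonal(dists, np.inf)
    neigh = np.argsort(dists, axis=1)[:, :k]  # within-Dr neighbour lists

    n_new = int(round(params.over_percent * rare.size))
    rng = np.random.default_rng(params.seed)
    rows, targets, prov_new = [], [], []
    for _ in range(n_new):
        si = int(rng.integers(rare.size))
        ni = int(neigh[si, rng.integers(k)])
        seed_row, nb_row = Xr[si], Xr[ni]
        u = rng.uniform()
        new = seed_row.copy()
        if numeric_cols:
            cols = np.asarray(numeric_cols)
            new[cols] = seed_row[cols] + u * (nb_row[cols] - seed_row[cols])
        for cols in onehot_groups:
            source = nb_row if rng.uniform() < 0.5 else seed_row
            new[cols] = source[cols]
        d_seed = float(np.linalg.norm(new - seed_row))
        d_nb = float(np.linalg.norm(new - nb_row))
        ys, yn = y[rare[si]], y[rare[ni]]
        if d_seed + d_nb == 0.0:
            y_new = 0.5 * (ys + yn)
        else:
            y_new = (d_nb * ys + d_seed * yn) / (d_seed + d_nb)
        rows.append(new)
        targets.append(y_new)
        prov_new.append(("synthetic", int(idx[rare[si]]), int(idx[rare[ni]])))

    prov = [("original", int(i)) for i in idx] + prov_new
    X_out = np.vstack([X] + [np.asarray(rows)]) if rows else X.copy()
    y_out = np.concatenate([y, np.asarray(targets)]) if targets else y.copy()
    return ResampledTrainSet(X_out, y_out, prov, "smoter", params)


def wercs(
    X: np.ndarray,
    y: np.ndarray,
    relevance: RelevanceFunction,
    params: ResampleParams = ResampleParams(),
    indices: np.ndarray | None = None,
) -> ResampledTrainSet:
    """Weighted relevance-based combination of over- and undersampling.

    No threshold: ``⌈wercs_over_frac · n⌉`` replicas are drawn with
    replacement with probability ∝ Φ(y) and appended, and
    ``⌈wercs_under_frac · n⌉`` rows are removed (without replacement)
    with probability ∝ 1 − Φ(y).
    """
    X, y = _as_xy(X, y)
    if y.size < 2:
        raise ConfigError("wercs needs at least 2 rows")
    idx = _indices(y, indices)
    phi = np.atleast_1d(relevance(y))
    rng = np.random.default_rng(params.seed)
    n = y.size

    n_over = math.ceil(params.wercs_over_frac * n)
    picks = np.empty(0, dtype=int)
    if n_over > 0:
        total = phi.sum()
        if total == 0:
            logger.warning("wercs: all relevance values are 0; no rows replicated")
            n_over = 0
        else:
            picks = rng.choice(n, size=n_over, replace=True, p=phi / total)

    n_under = math.ceil(params.wercs_under_frac * n)
    removed = np.empty(0, dtype=int)
    if n_under > 0:
        w = 1.0 - phi
        removable = np.flatnonzero(w > 0)
        n_under = min(n_under, removable.size, n - 1)
        if n_under > 0:
            p = w[removable] / w[removable].sum()
            removed = rng.choice(removable, size=n_under, replace=False, p=p)

    keep = np.setdiff1d(np.arange(n), removed)
    prov = [("original", int(idx[i])) for i in keep]
    prov += [("replica", int(idx[p])) for p in picks]
    X_out = np.vstack([X[keep], X[picks]]) if picks.size else X[keep].copy()
    y_out = np.concatenate([y[keep], y[picks]])
    return ResampledTrainSet(X_out, y_out, prov, "wercs", params)


def resample(
    strategy: str,
    X: np.ndarray,
    y: np.ndarray,
    relevance: RelevanceFunction,
    params: ResampleParams = ResampleParams(),
    feature_kinds: list[tuple[str, str, list[int]]] | None = None,
    indices: np.ndarray | None = None,
) -> ResampledTrainSet:
    """Dispatch to one of the three strategies by name."""
    if strategy == "random_over":
        return random_oversample(X, y, relevance, params, indices)
    if strategy == "smoter":
        return smoter(X, y, relevance, params, feature_kinds, indices)
    if strategy == "wercs":
        return wercs(X, y, relevance, params, indices)
    raise ConfigError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")


def distribution_diagnostics(
    y_before: np.ndarray,
    y_after: np.ndarray,
    n_bins: int = 30,
) -> tuple[float, float, float, float]:
    """Variance and Shannon entropy of the target before/after resampling.

    Entropy (natural log) is computed on equal-width histograms over
    shared bin edges spanning the pooled range, so the two values are
    directly comparable.  Returns (variance_before, variance_after,
    entropy_before, entropy_after).
    """
    if n_bins < 2:
        raise ConfigError(f"n_bins must be >= 2, got {n_bins}")
    yb = np.asarray(y_before, dtype=float).ravel()
    ya = np.asarray(y_after, dtype=float).ravel()
    if yb.size == 0 or ya.size == 0:
        raise ConfigError("both target vectors must be nonempty")
    lo = min(yb.min(), ya.min())
    hi = max(yb.max(), ya.max())
    if hi == lo:
        hi = lo + 1.0  # single-valued targets occupy one bin
    edges = np.linspace(lo, hi, n_bins + 1)

    def entropy(v: np.ndarray) -> float:
        counts, _ = np.histogram(v, bins=edges)
        p = counts[counts > 0] / v.size
        return float(-np.sum(p * np.log(p)))

    var_b = float(np.var(yb, ddof=1)) if yb.size > 1 else 0.0
    var_a = float(np.var(ya, ddof=1)) if ya.size > 1 else 0.0
    return var_b, var_a, entropy(yb), entropy(ya)


@dataclass
class KdeOverlay:
    """Evaluated densities and (optionally) the path of the saved figure."""

    grid: np.ndarray
    density_before: np.ndarray
    density_after: np.ndarray
    path: str | None = None


def kde_overlay(
    y_before: np.ndarray,
    y_after: np.ndarray,
    path: str | None = None,
    title: str | None = None,
    n_grid: int = 512,
) -> KdeOverlay:
    """Gaussian-kernel density overlay of original vs resampled targets.

    Bandwidth follows Scott's rule of thumb.  When ``path`` is given a
    labelled two-curve figure is written there.
    """
    yb = np.asarray(y_before, dtype=float).ravel()
    ya = np.asarray(y_after, dtype=float).ravel()
    if yb.size == 0 or ya.size == 0:
        raise ConfigError("both target vectors must be nonempty")
    lo = min(yb.min(), ya.min())
    hi = max(yb.max(), ya.max())
    pad = 0.25 * (hi - lo) if hi > lo else 1.0
    grid = np.linspace(lo - pad, hi + pad, n_grid)
    dens_b = gaussian_kde(yb)(grid)
    dens_a = gaussian_kde(ya)(grid)
    if path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(grid, dens_b, color="tab:green", label="original")
        ax.plot(grid, dens_a, color="tab:red", label="resampled")
        ax.set_xlabel("RPA")
        ax.set_ylabel("density")
        if title:
            ax.set_title(title)
        ax.legend()
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return KdeOverlay(grid=grid, density_before=dens_b, density_after=dens_a,
                      path=str(path) if path is not None else None)
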