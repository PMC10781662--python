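"""Encoding, normalization and the stratified train/test split.

Categorical factors are one-hot encoded (full encoding, no dropped
level, so each level can surface as its own feature in importance
tables); numerical factors are min-max normalized to [0, 1] with the
train-time (Xmin, Xmax) reused verbatim at prediction time — the only
leakage-free choice.  The split stratifies on quantile bins of the
continuous target so the train and test target distributions match.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.preprocessing import OneHotEncoder

from .exceptions import ConfigError, DimensionError
from .io_model import CoronaDataset

logger = logging.getLogger(__name__)


@dataclass
class EncodedMatrix:
    """A fully numeric design matrix with provenance of every column.

    ``parent_of`` maps each encoded column name back to the factor it
    came from; ``norm_params`` holds the (Xmin, Xmax) pair used for
    each numeric factor so new rows can be encoded consistently.
    """

    X: np.ndarray
    encoded_names: list[str]
    parent_of: dict[str, str]
    norm_params: dict[str, tuple[float, float]] = field(default_factory=dict)
    categories: dict[str, list[str]] = field(default_factory=dict)

    def columns_of(self, factor: str) -> list[int]:
        return [i for i, c in enumerate(self.encoded_names) if self.parent_of[c] == factor]

    def feature_groups(self) -> list[tuple[str, str, list[int]]]:
        """Per-factor column groups: (factor, kind, column indices).

        Kind is ``"onehot"`` for categorical groups (to be inherited
        atomically during interpolation-based resampling) and
        ``"numeric"`` for single normalized columns.
        """
        groups: list[tuple[str, str, list[int]]] = []
        seen: dict[str, list[int]] = {}
        order: list[str] = []
        for i, c in enumerate(self.encoded_names):
            parent = self.parent_of[c]
            if parent not in seen:
                seen[parent] = []
                order.append(parent)
            seen[parent].append(i)
        for parent in order:
            kind = "onehot" if parent in self.categories else "numeric"
            groups.append((parent, kind, seen[parent]))
        return groups


def min_max_normalize(
    values: np.ndarray,
    params: tuple[float, float] | None = None,
) -> tuple[np.ndarray, tuple[float, float]]:
    """Rescale values to [0, 1] by (Xi - Xmin) / (Xmax - Xmin).

    When ``params`` is given (prediction time) those bounds are reused
    and nothing is clipped: out-of-range outputs are allowed and
    logged.  A constant column (train time) maps to all zeros with a
    warning, since the transform is undefined there.
    """
    v = np.asarray(values, dtype=float)
    if params is None:
        xmin, xmax = float(np.min(v)), float(np.max(v))
        if xmax == xmin:
            logger.warning("constant numeric column (value %g): normalized to 0.0", xmin)
            return np.zeros_like(v), (xmin, xmax)
    else:
        xmin, xmax = params
        if xmax == xmin:
            return np.zeros_like(v), (xmin, xmax)
    out = (v - xmin) / (xmax - xmin)
    if params is not None and (np.any(out < 0) or np.any(out > 1)):
        logger.warning(
            "%d value(s) outside the training range [%g, %g]",
            int(np.sum((out < 0) | (out > 1))), xmin, xmax,
        )
    return out, (xmin, xmax)


def one_hot_encode(data: CoronaDataset) -> EncodedMatrix:
    """One-hot encode the categorical factors (full, non-dropped).

    One binary column per (factor, level), levels in lexicographic
    order; numeric factors are not included.
    """
    cat = data.categorical_factors
    if not cat:
        return EncodedMatrix(
            X=np.empty((data.n_rows, 0)), encoded_names=[], parent_of={}
        )
    enc = OneHotEncoder(sparse_output=False, handle_unknown="ignore", dtype=float)
    X = enc.fit_transform(data.factors[cat])
    names: list[str] = []
    parent: dict[str, str] = {}
    categories: dict[str, list[str]] = {}
    for f, levels in zip(cat, enc.categories_):
        categories[f] = [str(lv) for lv in levels]
        for lv in levels:
            name = f"{f}={lv}"
            names.append(name)
            parent[name] = f
    return EncodedMatrix(X=X, encoded_names=names, parent_of=parent, categories=categories)


class CoronaEncoder:
    """Fit-once encoder combining one-hot and min-max normalization.

    Fit on the training split; ``transform`` then encodes any rows
    (test split or brand-new nanoparticle records) with the stored
    levels and normalization bounds.  Unseen categorical levels encode
    as an all-zero group with a warning.
    """

    def __init__(self) -> None:
        self._onehot: OneHotEncoder | None = None
        self.categorical: list[str] = []
        self.numerical: list[str] = []
        self.encoded_names: list[str] = []
        self.parent_of: dict[str, str] = {}
        self.norm_params: dict[str, tuple[float, float]] = {}
        self.categories: dict[str, list[str]] = {}

    def fit(self, data: CoronaDataset) -> "CoronaEncoder":
        self.categorical = data.categorical_factors
        self.numerical = data.numerical_factors
        encoded = one_hot_encode(data)
        self.encoded_names = list(encoded.encoded_names)
        self.parent_of = dict(encoded.parent_of)
        self.categories = dict(encoded.categories)
        if self.categorical:
            self._onehot = OneHotEncoder(
                sparse_output=False,
                handle_unknown="ignore",
                dtype=float,
                categories=[self.categories[f] for f in self.categorical],
            )
            self._onehot.fit(data.factors[self.categorical])
        for f in self.numerical:
            _, params = min_max_normalize(data.factors[f].to_numpy())
            self.norm_params[f] = params
            self.encoded_names.append(f)
            self.parent_of[f] = f
        return self

    def transform(self, factors: pd.DataFrame) -> EncodedMatrix:
        if not self.encoded_names:
            raise ConfigError("encoder is not fitted")
        missing = [f for f in self.categorical + self.numerical if f not in factors.columns]
        if missing:
            raise DimensionError(f"rows lack factors required by the encoder: {missing}")
        parts: list[np.ndarray] = []
        if self.categorical:
            block = self._onehot.transform(factors[self.categorical])
            # an all-zero one-hot group marks an unseen level
            start = 0
            for f in self.categorical:
                width = len(self.categories[f])
                group = block[:, start : start + width]
                n_unseen = int(np.sum(group.sum(axis=1) == 0))
                if n_unseen:
                    logger.warning(
                        "%d row(s) carry an unseen level of %r; encoded as all-zero group",
                        n_unseen, f,
                    )
                start += width
            parts.append(block)
        for f in self.numerical:
            col, _ = min_max_normalize(factors[f].to_numpy(), self.norm_params[f])
            parts.append(col[:, None])
        X = np.hstack(parts) if parts else np.empty((len(factors), 0))
        return EncodedMatrix(
            X=X,
            encoded_names=list(self.encoded_names),
            parent_of=dict(self.parent_of),
            norm_params=dict(self.norm_params),
            categories=dict(self.categories),
        )

    def fit_transform(self, data: CoronaDataset) -> EncodedMatrix:
        return self.fit(data).transform(data.factors)


@dataclass(frozen=True)
class SplitIndices:
    """A disjoint, exhaustive train/test partition of row indices."""

    train: np.ndarray
    test: np.ndarray
    n_strata: int

    def __post_init__(self) -> None:
        train, test = set(self.train.tolist()), set(self.test.tolist())
        if train & test:
            raise ConfigError("train and test indices overlap")


def stratified_split(
    targets: np.ndarray,
    ratio: float = 0.1,
    n_strata: int = 10,
    seed: int = 0,
) -> SplitIndices:
    """Quantile-stratified split of a continuous target.

    Rows are binned into ``n_strata`` quantile bins of the target and a
    seeded ``ratio`` fraction of each bin goes to the test side, so the
    train and test target distributions are nearly identical even for
    heavily skewed targets.
    """
    if not 0 < ratio < 1:
        raise ConfigError(f"split ratio must be in (0, 1), got {ratio}")
    y = np.asarray(targets, dtype=float).ravel()
    n = y.size
    edges = np.unique(np.quantile(y, np.linspace(0, 1, n_strata + 1)[1:-1]))
    strata = np.searchsorted(edges, y, side="right")
    rng = np.random.default_rng(seed)
    test: list[int] = []
    for s in np.unique(strata):
        members = np.flatnonzero(strata == s)
        n_test = int(round(ratio * members.size))
        if n_test > 0:
            test.extend(rng.choice(members, size=n_test, replace=False).tolist())
    test_arr = np.sort(np.asarray(test, dtype=int))
    mask = np.ones(n, dtype=bool)
    mask[test_arr] = False
    return SplitIndices(train=np.flatnonzero(mask), test=test_arr, n_strata=n_strata)
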