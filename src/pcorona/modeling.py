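"""Per-protein Random Forest models, evaluation metrics, learning
curves, feature importance and the resampling ablation harness.

The forest itself is the standard bagged-tree regressor (predictions
are the across-tree mean); the package's contribution is everything
around it: relevance-guided rebalancing of each protein's training
set, a leakage-audited four-arm ablation (no resampling vs the three
strategies), and Gini-importance aggregation from one-hot columns back
to their parent factors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

from .exceptions import (
    ConfigError,
    DegenerateInputError,
    DimensionError,
    PcoronaError,
    TrainingError,
)
from .io_model import CoronaDataset
from .preprocessing import CoronaEncoder, EncodedMatrix, stratified_split
from .relevance import RelevanceFunction, default_control_points, pchip_fit
from .resampling import ResampledTrainSet, ResampleParams, resample

logger = logging.getLogger(__name__)

ABLATION_ARMS = ("none", "random_over", "smoter", "wercs")


@dataclass(frozen=True)
class ModelConfig:
    """Random-forest and evaluation settings.

    Defaults: 500 trees, unbounded depth, all features considered at
    each split, and a minimum leaf size of 10 — a standard
    regularization level for noisy tabular data of a few hundred rows.
    The leaf floor matters beyond generalization: it makes the
    forest's resolution in any target region proportional to that
    region's sample weight, which is the imbalance pathology that
    relevance-guided resampling is designed to correct.  10-fold
    cross-validation for learning curves.
    """

    n_trees: int = 500
    max_depth: int | None = None
    min_leaf: int = 10
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ConfigError("n_trees must be >= 1")
        if self.cv_folds < 2:
            raise ConfigError("cv_folds must be >= 2")


@dataclass
class FittedModel:
    """A fitted forest plus the metadata needed to encode new rows."""

    model: RandomForestRegressor
    encoded_names: list[str]
    parent_of: dict[str, str]
    encoder: CoronaEncoder | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict(X)


@dataclass
class EvaluationReport:
    """Aggregated results for one ablation arm."""

    strategy: str
    per_protein: dict[str, tuple[float, float]]  # protein -> (r2, rmse)
    mean_r2: float
    mean_rmse: float
    importances: dict[str, float] = field(default_factory=dict)
    learning_curve: list[tuple[int, float, float]] = field(default_factory=list)
    audit_passed: bool = True


def train_rf(
    train: ResampledTrainSet | EncodedMatrix | np.ndarray,
    targets: np.ndarray | None = None,
    config: ModelConfig = ModelConfig(),
    encoder: CoronaEncoder | None = None,
) -> FittedModel:
    """Fit a bagged-tree regressor; deterministic given ``config.seed``.

    Accepts a :class:`ResampledTrainSet` (targets included), an
    :class:`EncodedMatrix` plus targets, or a bare matrix plus targets.
    """
    names: list[str] = []
    parent: dict[str, str] = {}
    if isinstance(train, ResampledTrainSet):
        X, y = train.X, train.y
    elif isinstance(train, EncodedMatrix):
        X, names, parent = train.X, list(train.encoded_names), dict(train.parent_of)
        y = targets
    else:
        X, y = np.asarray(train, dtype=float), targets
    if y is None:
        raise ConfigError("targets required unless a ResampledTrainSet is given")
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] < 10:
        raise TrainingError(f"need at least 10 training rows, got {X.shape[0]}")
    if encoder is not None and not names:
        names, parent = list(encoder.encoded_names), dict(encoder.parent_of)
    model = RandomForestRegressor(
        n_estimators=config.n_trees,
        max_depth=config.max_depth,
        min_samples_leaf=config.min_leaf,
        random_state=config.seed,
        n_jobs=1,
    )
    model.fit(X, y)
    return FittedModel(model=model, encoded_names=names, parent_of=parent, encoder=encoder)


def r_squared(true: np.ndarray, pred: np.ndarray, literal: bool = False) -> float:
    """Coefficient of determination as the squared Pearson correlation.

    ``literal=True`` instead evaluates the unsquared covariance-over-
    variances ratio Σ(r−r̄)(p−p̄) / (Σ(r−r̄)² Σ(p−p̄)²), kept for
    auditability of the alternative reading of the formula.
    """
    r = np.asarray(true, dtype=float).ravel()
    p = np.asarray(pred, dtype=float).ravel()
    if r.size != p.size:
        raise DimensionError(f"length mismatch: {r.size} vs {p.size}")
    if r.size < 2:
        raise DegenerateInputError("r_squared needs at least 2 samples")
    rc, pc = r - r.mean(), p - p.mean()
    ssr, ssp = float(np.sum(rc**2)), float(np.sum(pc**2))
    if ssr == 0 or ssp == 0:
        raise DegenerateInputError("r_squared undefined for a constant vector")
    cov = float(np.sum(rc * pc))
    if literal:
        return cov / (ssr * ssp)
    return cov * cov / (ssr * ssp)


def rmse(true: np.ndarray, pred: np.ndarray) -> float:
    """Root mean squared error."""
    r = np.asarray(true, dtype=float).ravel()
    p = np.asarray(pred, dtype=float).ravel()
    if r.size != p.size:
        raise DimensionError(f"length mismatch: {r.size} vs {p.size}")
    if r.size == 0:
        raise DimensionError("rmse needs at least 1 sample")
    return float(np.sqrt(np.mean((r - p) ** 2)))


def _derived_seed(base: int, *salts: int) -> int:
    s = base & 0x7FFFFFFF
    for salt in salts:
        s = (s * 1000003 + salt + 1) % 2147483629
    return s


def _fit_relevance(y_train: np.ndarray) -> RelevanceFunction:
    return pchip_fit(default_control_points(y_train))


def learning_curve(
    X: np.ndarray,
    y: np.ndarray,
    config: ModelConfig = ModelConfig(),
    resampler: str | None = None,
    resample_params: ResampleParams = ResampleParams(),
    feature_kinds: list[tuple[str, str, list[int]]] | None = None,
    sizes: Sequence[int] | None = None,
) -> list[tuple[int, float, float]]:
    """Cross-validated RMSE as a function of training-set size.

    For each requested size, every CV fold subsamples that many rows
    from its training portion, optionally rebalances them with the
    requested strategy (resampling happens inside the fold, on the
    training portion only), fits a forest, and scores RMSE on the held
    fold.  Returns (size, mean RMSE, sd RMSE) triples.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    max_train = n - n // config.cv_folds
    if sizes is None:
        lo = max(20, max_train // 5)
        sizes = np.unique(np.linspace(lo, max_train, 5, dtype=int)).tolist()
    usable = [int(s) for s in sizes if s <= max_train]
    if len(usable) < len(list(sizes)):
        logger.warning("learning_curve: grid truncated to sizes <= %d", max_train)
    kf = KFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
    folds = list(kf.split(X))
    curve: list[tuple[int, float, float]] = []
    for size in usable:
        errs = []
        for f, (tr, va) in enumerate(folds):
            rng = np.random.default_rng(_derived_seed(config.seed, size, f))
            sub = rng.permutation(tr)[:size]
            X_tr, y_tr = X[sub], y[sub]
            if resampler is not None and resampler != "none":
                rel = _fit_relevance(y_tr)
                params = ResampleParams(
                    threshold=resample_params.threshold,
                    over_percent=resample_params.over_percent,
                    k_neighbors=resample_params.k_neighbors,
                    wercs_over_frac=resample_params.wercs_over_frac,
                    wercs_under_frac=resample_params.wercs_under_frac,
                    seed=_derived_seed(resample_params.seed, size, f),
                )
                rs = resample(resampler, X_tr, y_tr, rel, params, feature_kinds)
                X_tr, y_tr = rs.X, rs.y
            fitted = train_rf(X_tr, y_tr, config)
            errs.append(rmse(y[va], fitted.predict(X[va])))
        curve.append((size, float(np.mean(errs)), float(np.std(errs))))
    return curve


def aggregate_importance(
    model: RandomForestRegressor | FittedModel,
    encoded_names: Sequence[str] | None = None,
    parent_of: Mapping[str, str] | None = None,
) -> dict[str, float]:
    """Sum impurity importances of encoded columns into parent factors."""
    if isinstance(model, FittedModel):
        encoded_names = encoded_names or model.encoded_names
        parent_of = parent_of or model.parent_of
        model = model.model
    imps = model.feature_importances_
    if encoded_names is None or len(encoded_names) != imps.size:
        raise DimensionError("encoded_names must align with the model's features")
    out: dict[str, float] = {}
    for name, w in zip(encoded_names, imps):
        parent = parent_of[name] if parent_of else name
        out[parent] = out.get(parent, 0.0) + float(w)
    return out


def feature_importance(
    models: Iterable[FittedModel],
    parent_of: Mapping[str, str] | None = None,
    threshold: float = 0.01,
    level_wise: bool = False,
) -> dict[str, float]:
    """Mean Gini importance per factor across per-protein models.

    Encoded one-hot columns are summed into their parent factor
    (``level_wise=True`` keeps each level as its own feature instead,
    for the secondary level-resolved table), importances are averaged
    across models, factors with mean importance > ``threshold`` are
    retained, and the result is sorted descending.
    """
    sums: dict[str, float] = {}
    n_models = 0
    for fm in models:
        n_models += 1
        if level_wise:
            per = {name: float(w) for name, w in zip(fm.encoded_names, fm.model.feature_importances_)}
        else:
            per = aggregate_importance(fm, parent_of=parent_of or fm.parent_of)
        for k, v in per.items():
            sums[k] = sums.get(k, 0.0) + v
    if n_models == 0:
        raise ConfigError("no fitted models given")
    means = {k: v / n_models for k, v in sums.items()}
    kept = {k: v for k, v in means.items() if v > threshold}
    return dict(sorted(kept.items(), key=lambda kv: kv[1], reverse=True))


def filter_importances(importances: Mapping[str, float], threshold: float = 0.01) -> dict[str, float]:
    """Apply the importance cutoff and sort descending."""
    kept = {k: v for k, v in importances.items() if v > threshold}
    return dict(sorted(kept.items(), key=lambda kv: kv[1], reverse=True))


def run_ablation(
    dataset: CoronaDataset,
    strategies: Sequence[str] = ABLATION_ARMS,
    config: ModelConfig = ModelConfig(),
    resample_params: ResampleParams = ResampleParams(),
    test_ratio: float = 0.1,
    n_strata: int = 10,
    return_models: bool = False,
) -> list[EvaluationReport] | tuple[list[EvaluationReport], dict[str, dict[str, FittedModel]]]:
    """Train and evaluate every arm on every protein target.

    For each protein: a quantile-stratified 9:1 split of that protein's
    RPA is drawn, the encoder (one-hot levels and min-max bounds) is
    fitted on the train side only, the train side alone is resampled,
    a forest is fitted, and R²/RMSE are measured on the untouched test
    side.  A provenance audit verifies that no resampled row derives
    from a test row.  Per-protein scores are aggregated by unweighted
    mean, and Gini importances (summed into parent factors) are
    averaged across proteins.
    """
    reports: list[EvaluationReport] = []
    models: dict[str, dict[str, FittedModel]] = {}
    proteins = dataset.protein_ids
    rpa = dataset.rpa.to_numpy(dtype=float)

    # splits and encoders are shared across arms so arms differ only in resampling
    per_protein_setup = []
    for j, pid in enumerate(proteins):
        y = rpa[:, j]
        split = stratified_split(y, ratio=test_ratio, n_strata=n_strata,
                                 seed=_derived_seed(config.seed, j))
        train_data = CoronaDataset(
            factors=dataset.factors.iloc[split.train],
            rpa=dataset.rpa.iloc[split.train],
            factor_kinds=dict(dataset.factor_kinds),
        )
        encoder = CoronaEncoder().fit(train_data)
        enc_train = encoder.transform(dataset.factors.iloc[split.train])
        enc_test = encoder.transform(dataset.factors.iloc[split.test])
        rel = _fit_relevance(y[split.train])
        per_protein_setup.append((pid, j, split, encoder, enc_train, enc_test, rel))

    for arm_idx, arm in enumerate(strategies):
        per_protein: dict[str, tuple[float, float]] = {}
        importance_sum: dict[str, float] = {}
        models[arm] = {}
        audit_ok = True
        for pid, j, split, encoder, enc_train, enc_test, rel in per_protein_setup:
            y = rpa[:, j]
            y_train, y_test = y[split.train], y[split.test]
            if arm == "none":
                X_fit, y_fit = enc_train.X, y_train
            else:
                params = ResampleParams(
                    threshold=resample_params.threshold,
                    over_percent=resample_params.over_percent,
                    k_neighbors=resample_params.k_neighbors,
                    wercs_over_frac=resample_params.wercs_over_frac,
                    wercs_under_frac=resample_params.wercs_under_frac,
                    seed=_derived_seed(config.seed, j, arm_idx),
                )
                rs = resample(arm, enc_train.X, y_train, rel, params,
                              enc_train.feature_groups(), indices=split.train)
                leaked = rs.origin_rows() & set(split.test.tolist())
                if leaked:
                    audit_ok = False
                    raise PcoronaError(
                        f"leakage audit failed for protein {pid}, arm {arm}: "
                        f"test rows {sorted(leaked)} appear in the resampled train set"
                    )
                X_fit, y_fit = rs.X, rs.y
            fitted = train_rf(
                X_fit, y_fit,
                ModelConfig(n_trees=config.n_trees, max_depth=config.max_depth,
                            min_leaf=config.min_leaf, cv_folds=config.cv_folds,
                            seed=_derived_seed(config.seed, j, arm_idx, 7)),
            )
            fitted.encoded_names = list(enc_train.encoded_names)
            fitted.parent_of = dict(enc_train.parent_of)
            fitted.encoder = encoder
            pred = fitted.predict(enc_test.X)
            try:
                r2 = r_squared(y_test, pred)
            except DegenerateInputError:
                r2 = float("nan")
            per_protein[pid] = (r2, rmse(y_test, pred))
            for k, v in aggregate_importance(fitted).items():
                importance_sum[k] = importance_sum.get(k, 0.0) + v
            if return_models:
                models[arm][pid] = fitted
        r2s = np.array([v[0] for v in per_protein.values()])
        rmses = np.array([v[1] for v in per_protein.values()])
        reports.append(
            EvaluationReport(
                strategy=arm,
                per_protein=per_protein,
                mean_r2=float(np.nanmean(r2s)),
                mean_rmse=float(np.mean(rmses)),
                importances={k: v / len(proteins) for k, v in importance_sum.items()},
                audit_passed=audit_ok,
            )
        )
    if return_models:
        return reports, models
    return reports


def summary_frame(reports: Sequence[EvaluationReport]) -> pd.DataFrame:
    """One row per arm: mean R² and mean RMSE over proteins."""
    return pd.DataFrame(
        {
            "strategy": [r.strategy for r in reports],
            "mean_r2": [r.mean_r2 for r in reports],
            "mean_rmse": [r.mean_rmse for r in reports],
        }
    )


def per_protein_frame(reports: Sequence[EvaluationReport]) -> pd.DataFrame:
    """Long table: (protein, strategy, r2, rmse) for every arm."""
    rows = []
    for rep in reports:
        for pid, (r2, e) in rep.per_protein.items():
            rows.append({"protein": pid, "strategy": rep.strategy, "r2": r2, "rmse": e})
    return pd.DataFrame(rows)


def predict_new(
    models: Mapping[str, FittedModel],
    new_rows: pd.DataFrame,
) -> np.ndarray:
    """Predict per-protein RPA for new nanoparticle factor records.

    Rows are encoded with each model's stored train-time levels and
    normalization bounds; unseen categorical levels encode as all-zero
    one-hot groups (with a warning from the encoder).  Returns an
    (n_rows, n_proteins) matrix in the mapping's protein order.
    """
    out = np.empty((len(new_rows), len(models)))
    for j, (pid, fm) in enumerate(models.items()):
        if fm.encoder is None:
            raise ConfigError(f"model for {pid!r} carries no encoder; cannot encode new rows")
        enc = fm.encoder.transform(new_rows)
        out[:, j] = fm.predict(enc.X)
    return out
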