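"""Per-timepoint surrogate models for the proprietary lesion indices.

The two-step design: (1) on cohorts where the index value is known at
every timepoint (here: the ground-truth oracle on synthetic traces; in
the clinic: mapping-system exports), train regressors that predict the
index from trace features; (2) apply them to traces from a system that
does not report the index, obtaining a predicted index series for every
timepoint and hence the RF application duration each index-based
stopping rule would have produced.

Feature sets mirror each formula's inputs:

* AI: elapsed time tau, instantaneous contact force, cumulative
  force-time integral (Simpson), power;
* LSI: tau, 6 s windowed contact force, 6 s windowed RF current, power.

Model families: random forest, gradient boosting (histogram-based),
ridge, lasso, elastic net.  Hyperparameters are grid-searched with
lesion-grouped k-fold cross-validation (row-level splits would leak
near-duplicate neighbouring timepoints of the same lesion); evaluation
uses a lesion-grouped 70/30 holdout.  The skewed LSI target can be
quantile-transformed for training, with predictions mapped back through
the inverse transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from numpy.typing import NDArray
from sklearn.base import BaseEstimator, clone
from sklearn.ensemble import HistGradientBoostingRegressor, RandomForestRegressor
from sklearn.isotonic import IsotonicRegression
from sklearn.linear_model import ElasticNet, Lasso, Ridge
from sklearn.metrics import mean_absolute_error, r2_score
from sklearn.model_selection import GridSearchCV, GroupKFold, GroupShuffleSplit
from sklearn.preprocessing import QuantileTransformer

from .metrics import IndexSeries, force_time_integral, rf_current, sliding_window_mean
from .processing import AblationTrace, _moving_mean

__all__ = [
    "TimepointTable",
    "SurrogateFit",
    "FEATURE_COLUMNS",
    "timepoint_features",
    "build_training_table",
    "quantile_transform_target",
    "tune_and_train",
    "evaluate_holdout",
    "fit_surrogate",
    "predict_index_series",
    "surrogate_index_fn",
]

Family = Literal["random_forest", "gradient_boosting", "ridge", "lasso", "elastic_net"]

FEATURE_COLUMNS: dict[str, list[str]] = {
    "AI": ["tau_s", "cf_g", "fti_gs", "power_w"],
    "LSI": ["tau_s", "cf_window6_g", "current_window6_ma", "power_w"],
}

#: small implementer-chosen default grids: tree count/depth for ensembles,
#: regularization strength for the linear families
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "random_forest": {"n_estimators": [30, 60], "max_depth": [12, None]},
    "gradient_boosting": {"max_iter": [100, 200], "max_depth": [None, 6]},
    "ridge": {"alpha": [0.01, 0.1, 1.0, 10.0]},
    "lasso": {"alpha": [0.001, 0.01, 0.1, 1.0]},
    "elastic_net": {"alpha": [0.001, 0.01, 0.1, 1.0], "l1_ratio": [0.2, 0.5, 0.8]},
}


def _make_estimator(family: Family, seed: int) -> BaseEstimator:
    if family == "random_forest":
        return RandomForestRegressor(
            n_estimators=50, min_samples_leaf=2, n_jobs=1, random_state=seed
        )
    if family == "gradient_boosting":
        return HistGradientBoostingRegressor(random_state=seed)
    if family == "ridge":
        return Ridge(alpha=1.0, random_state=seed)
    if family == "lasso":
        return Lasso(alpha=0.01, random_state=seed, max_iter=5000)
    if family == "elastic_net":
        return ElasticNet(alpha=0.01, random_state=seed, max_iter=5000)
    raise ValueError(f"unknown model family {family!r}")


# ---------------------------------------------------------------------------
# training tables
# ---------------------------------------------------------------------------

@dataclass
class TimepointTable:
    """Per-timepoint feature/target rows plus a column manifest."""

    data: pd.DataFrame
    kind: Literal["AI", "LSI"]
    feature_columns: list[str]
    target_column: str = "target"

    def __post_init__(self) -> None:
        missing = set(self.feature_columns + [self.target_column, "lesion_key"]) - set(
            self.data.columns
        )
        if missing:
            raise ValueError(f"TimepointTable missing columns {sorted(missing)}")
        if not np.isfinite(self.data[self.target_column]).all():
            raise ValueError("TimepointTable: target must be finite")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def X(self) -> NDArray[np.float64]:
        return self.data[self.feature_columns].to_numpy(dtype=float)

    @property
    def y(self) -> NDArray[np.float64]:
        return self.data[self.target_column].to_numpy(dtype=float)

    @property
    def groups(self) -> NDArray:
        """Lesion group labels, unique across procedures."""
        return self.data["lesion_key"].to_numpy()


def timepoint_features(trace: AblationTrace, window_s: float = 6.0) -> pd.DataFrame:
    """All per-timepoint features for one uniform-grid trace.

    RF current is derived from a lightly smoothed LI (centered moving
    mean, no trim, so features stay defined from tau = 0); windowed
    columns are 6 s trailing means.
    """
    t = np.asarray(trace.time_s, dtype=float)
    tau = t - t[0]
    fs = 1.0 / float(np.mean(np.diff(t)))
    half = max(1, int(round(1.5 * fs)) // 2)
    li_smooth = _moving_mean(np.asarray(trace.li_ohm, dtype=float), half, "centered")
    current = rf_current(trace.power_w, li_smooth)
    return pd.DataFrame({
        "lesion_id": trace.lesion_id,
        "lesion_key": f"{trace.procedure_id}:{trace.lesion_id}",
        "tau_s": tau,
        "cf_g": trace.cf_g,
        "fti_gs": force_time_integral(trace.cf_g, t),
        "power_w": trace.power_w,
        "current_ma": current,
        "cf_window6_g": sliding_window_mean(trace.cf_g, t, window_s),
        "current_window6_ma": sliding_window_mean(current, t, window_s),
    })


def build_training_table(
    pairs: Iterable[tuple[AblationTrace, IndexSeries]],
    kind: Literal["AI", "LSI"],
    downsample_stride: int | None = None,
) -> TimepointTable:
    """Expand indexed traces into the per-timepoint training table.

    ``pairs`` yields (uniform-grid trace, index series on the same grid);
    the series value becomes the regression target.  ``downsample_stride``
    keeps every k-th timepoint per lesion, preserving temporal order.
    """
    if kind not in FEATURE_COLUMNS:
        raise ValueError(f"kind must be 'AI' or 'LSI', got {kind!r}")
    stride = downsample_stride or 1
    if stride < 1:
        raise ValueError("downsample_stride must be >= 1")
    frames = []
    for trace, series in pairs:
        if series.kind != kind:
            raise ValueError(f"index series kind {series.kind} != requested {kind}")
        if len(series.value) != len(trace.time_s):
            raise ValueError("index series not aligned to trace grid")
        feats = timepoint_features(trace)
        feats["target"] = np.asarray(series.value, dtype=float)
        frames.append(feats.iloc[::stride])
    if not frames:
        raise ValueError("build_training_table: no traces given")
    data = pd.concat(frames, ignore_index=True)
    return TimepointTable(data=data, kind=kind, feature_columns=FEATURE_COLUMNS[kind])


# ---------------------------------------------------------------------------
# target transform
# ---------------------------------------------------------------------------

def quantile_transform_target(
    table: TimepointTable, seed: int = 0
) -> tuple[TimepointTable, QuantileTransformer]:
    """Quantile-map the target to a normal reference distribution.

    Returns the transformed table and the fitted transformer (whose
    ``inverse_transform`` is the inverse map).  Requires at least 10
    distinct target values; a constant target is rejected.
    """
    y = table.y.reshape(-1, 1)
    n_distinct = len(np.unique(y))
    if n_distinct < 2:
        raise ValueError("quantile transform: constant target")
    if n_distinct < 10:
        raise ValueError(
            f"quantile transform: need >= 10 distinct target values, got {n_distinct}"
        )
    qt = QuantileTransformer(
        n_quantiles=min(1000, len(y)),
        output_distribution="normal",
        subsample=1_000_000,
        random_state=seed,
    )
    y_t = qt.fit_transform(y).ravel()
    data = table.data.copy()
    data[table.target_column] = y_t
    return (
        TimepointTable(
            data=data,
            kind=table.kind,
            feature_columns=table.feature_columns,
            target_column=table.target_column,
        ),
        qt,
    )


# ---------------------------------------------------------------------------
# fitting and evaluation
# ---------------------------------------------------------------------------

@dataclass
class SurrogateFit:
    """A tuned surrogate regressor plus its training metadata."""

    kind: Literal["AI", "LSI"]
    family: Family
    model: BaseEstimator
    feature_columns: list[str]
    best_params: dict
    transform: QuantileTransformer | None
    seed: int
    folds: int
    grid: dict
    feature_ranges: pd.DataFrame  # index: feature, columns: lo, hi
    r2: float = float("nan")
    mae: float = float("nan")

    def predict(self, X: NDArray[np.float64]) -> NDArray[np.float64]:
        """Predict on raw feature rows, back-transforming if needed."""
        pred = self.model.predict(X)
        if self.transform is not None:
            pred = self.transform.inverse_transform(pred.reshape(-1, 1)).ravel()
        return pred


def _feature_ranges(table: TimepointTable) -> pd.DataFrame:
    X = table.data[table.feature_columns]
    return pd.DataFrame({"lo": X.min(), "hi": X.max()})


def tune_and_train(
    table: TimepointTable,
    family: Family,
    grid: dict[str, list] | None = None,
    folds: int = 10,
    seed: int = 0,
    use_quantile_transform: bool = False,
) -> SurrogateFit:
    """Grid-search hyperparameters by lesion-grouped CV and refit the best.

    A grid with a single configuration skips the search and is identical
    to a direct fit.  Deterministic for a fixed seed.
    """
    grid = grid if grid is not None else DEFAULT_GRIDS[family]
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("hyperparameter grid must be non-empty")
    if len(table) < folds:
        raise ValueError(f"table has {len(table)} rows < {folds} folds")
    if np.unique(table.y).size < 2:
        raise ValueError("degenerate single-value target; nothing to regress on")

    transform = None
    fit_table = table
    if use_quantile_transform:
        fit_table, transform = quantile_transform_target(table, seed=seed)

    est = _make_estimator(family, seed)
    n_configs = int(np.prod([len(v) for v in grid.values()]))
    n_groups = len(np.unique(fit_table.groups))
    if n_configs == 1:
        params = {k: v[0] for k, v in grid.items()}
        model = clone(est).set_params(**params)
        model.fit(fit_table.X, fit_table.y)
        best_params = params
    else:
        cv = GroupKFold(n_splits=min(folds, n_groups))
        search = GridSearchCV(est, grid, cv=cv, scoring="r2", n_jobs=1, refit=True)
        search.fit(fit_table.X, fit_table.y, groups=fit_table.groups)
        model = search.best_estimator_
        best_params = dict(search.best_params_)

    return SurrogateFit(
        kind=table.kind,
        family=family,
        model=model,
        feature_columns=list(table.feature_columns),
        best_params=best_params,
        transform=transform,
        seed=seed,
        folds=folds,
        grid=grid,
        feature_ranges=_feature_ranges(table),
    )


def holdout_split(
    table: TimepointTable, holdout_fraction: float = 0.30, seed: int = 0
) -> tuple[TimepointTable, TimepointTable]:
    """Deterministic lesion-grouped train/holdout split of a table."""
    if not 0.0 < holdout_fraction < 1.0:
        raise ValueError("holdout_fraction must lie in (0, 1)")
    gss = GroupShuffleSplit(n_splits=1, test_size=holdout_fraction, random_state=seed)
    train_idx, test_idx = next(gss.split(table.X, groups=table.groups))
    mk = lambda idx: TimepointTable(
        data=table.data.iloc[idx].reset_index(drop=True),
        kind=table.kind,
        feature_columns=table.feature_columns,
        target_column=table.target_column,
    )
    return mk(train_idx), mk(test_idx)


def evaluate_holdout(
    fit: SurrogateFit,
    table: TimepointTable,
    holdout_fraction: float = 0.30,
    seed: int = 0,
) -> tuple[float, float]:
    """R^2 and MAE on the lesion-grouped holdout rows of ``table``.

    The split is re-derived deterministically from ``seed``, so a fit
    trained on the train portion of the same split is scored on rows from
    lesions it never saw.  Predictions are back-transformed before
    scoring.  A single-lesion holdout triggers an instability warning.
    """
    _, holdout = holdout_split(table, holdout_fraction, seed)
    if len(np.unique(holdout.groups)) < 2:
        import warnings

        warnings.warn("holdout contains a single lesion; metrics are unstable")
    pred = fit.predict(holdout.X)
    return float(r2_score(holdout.y, pred)), float(mean_absolute_error(holdout.y, pred))


def fit_surrogate(
    table: TimepointTable,
    family: Family,
    grid: dict[str, list] | None = None,
    folds: int = 10,
    holdout_fraction: float = 0.30,
    seed: int = 0,
    use_quantile_transform: bool = False,
) -> SurrogateFit:
    """Full training protocol: grouped 70/30 split, grid-search CV on the
    training portion, holdout metrics stored on the returned fit."""
    train, _ = holdout_split(table, holdout_fraction, seed)
    fit = tune_and_train(
        train, family, grid=grid, folds=folds, seed=seed,
        use_quantile_transform=use_quantile_transform,
    )
    fit.r2, fit.mae = evaluate_holdout(fit, table, holdout_fraction, seed)
    return fit


# ---------------------------------------------------------------------------
# prediction on traces
# ---------------------------------------------------------------------------

def predict_index_series(
    fit: SurrogateFit,
    trace: AblationTrace,
    stride: int = 1,
    monotone: bool = False,
    guard_fraction: float = 0.01,
) -> tuple[IndexSeries, NDArray[np.bool_]]:
    """Predict the index at every (strided) timepoint of a uniform trace.

    Returns the predicted series and a per-row extrapolation flag: rows
    whose features leave the training range by more than
    ``guard_fraction`` of that range are flagged (never rejected).  With
    ``monotone=True`` an isotonic post-pass enforces a non-decreasing
    series.
    """
    feats = timepoint_features(trace).iloc[::stride]
    missing = set(fit.feature_columns) - set(feats.columns)
    if missing:
        raise ValueError(f"trace features missing columns {sorted(missing)}")
    X = feats[fit.feature_columns].to_numpy(dtype=float)
    pred = fit.predict(X)
    t = feats["tau_s"].to_numpy(dtype=float) + float(trace.time_s[0])

    lo = fit.feature_ranges["lo"].to_numpy()
    hi = fit.feature_ranges["hi"].to_numpy()
    slack = guard_fraction * np.maximum(hi - lo, 1e-12)
    flags = np.any((X < lo - slack) | (X > hi + slack), axis=1)

    if monotone:
        iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
        pred = iso.fit_transform(np.arange(len(pred)), pred)
    return IndexSeries(time_s=t, value=pred, kind=fit.kind), flags


def surrogate_index_fn(ai_fit: SurrogateFit, lsi_fit: SurrogateFit, stride: int = 1):
    """Index provider for :func:`rflesion.processing.process_traces` that
    evaluates trained surrogates instead of the ground-truth oracle.

    With ``stride > 1`` predictions are made on the strided grid (for
    speed) and linearly interpolated back onto the full trace grid, at a
    time-resolution cost of ``stride / fs`` seconds.
    """

    def one(fit: SurrogateFit, trace: AblationTrace) -> IndexSeries:
        series, _ = predict_index_series(fit, trace, stride=stride)
        if stride > 1:
            full_t = np.asarray(trace.time_s, dtype=float)
            series = IndexSeries(
                time_s=full_t,
                value=np.interp(full_t, series.time_s, series.value),
                kind=fit.kind,
            )
        return series

    def compute(trace: AblationTrace) -> tuple[IndexSeries, IndexSeries]:
        return one(ai_fit, trace), one(lsi_fit, trace)

    return compute
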