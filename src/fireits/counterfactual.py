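"""Stage 1 of the two-stage interrupted time series: counterfactual learning.

For one stratum x modality x cause daily count series, the pre-event
relationship between counts, calendar structure, and covariates is learned by
a hybrid of

* a **base component**: ordinary least-squares regression of counts on
  weekday indicators, annual harmonics of day-of-year, a within-season linear
  trend, season indicators, and a holiday flag — a transparent
  trend-plus-seasonality decomposition; and
* a **residual component**: gradient-boosted regression trees (XGBoost) fit
  to the base component's residuals on the full feature matrix, including the
  meteorological and wastewater covariates, capturing interactions and
  covariate effects the linear base cannot.

Hyperparameters are selected by rolling-origin cross-validation within the
pre-event period, minimizing mean RMSE over folds; the winning candidate is
refit on the full pre-period and used to predict the counterfactual (the
expected counts had the event not occurred) for every post-event date. No
post-event outcome ever enters fitting.
"""

from __future__ import annotations

import itertools
import json
from collections.abc import Sequence
from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd

__all__ = [
    "FeatureError",
    "FoldError",
    "FitError",
    "PredictionError",
    "CVConfig",
    "LearnerSpec",
    "CounterfactualFit",
    "PredictionResult",
    "default_holidays",
    "build_features",
    "rolling_origin_folds",
    "fit_counterfactual",
    "predict_counterfactual",
    "fit_cell",
    "fit_summary_json",
]


class FeatureError(ValueError):
    """Feature construction failed (covariate gaps, empty pre-period)."""


class FoldError(ValueError):
    """Not enough pre-period days for the requested fold layout."""


class FitError(RuntimeError):
    """Degenerate outcome or empty hyperparameter grid."""


class PredictionError(ValueError):
    """Post-period features do not match the fitted schema."""


MET_FEATURES = ("tmax", "tmin", "rhmax", "rhmin", "wind", "srad")
WW_FEATURES = ("ww_flu", "ww_rsv", "ww_sarscov2")
DOW_FEATURES = tuple(f"dow_{i}" for i in range(7))


def default_holidays(years: Sequence[int]) -> set[date]:
    """Thanksgiving (4th Thursday of November), Dec 24-25, Dec 31, Jan 1."""
    out: set[date] = set()
    for y in years:
        nov1 = date(y, 11, 1)
        first_thu = 1 + (3 - nov1.weekday()) % 7
        out.add(date(y, 11, first_thu + 21))
        out.add(date(y, 12, 24))
        out.add(date(y, 12, 25))
        out.add(date(y, 12, 31))
        out.add(date(y, 1, 1))
    return out


# ---------------------------------------------------------------------------
# feature construction
# ---------------------------------------------------------------------------


@dataclass
class FeatureSplit:
    """Pre/post feature matrices for one cell, split at the event date."""

    pre_X: pd.DataFrame
    pre_y: np.ndarray
    post_X: pd.DataFrame
    post_y: np.ndarray | None
    pre_dates: pd.DatetimeIndex
    post_dates: pd.DatetimeIndex


def build_features(
    series: pd.DataFrame | pd.Series,
    covariates: pd.DataFrame,
    event_date: date,
    holidays: set[date] | None = None,
) -> FeatureSplit:
    """Assemble the per-date feature matrix and split it at the event date.

    ``series`` is one cell's daily counts: either a Series indexed by date or
    a frame with ``date`` and ``count`` columns. Dates strictly before
    ``event_date`` form the pre matrix; ``event_date`` and after form the
    post matrix. Weekly wastewater covariates are forward-filled to daily
    resolution; any remaining missing covariate cell is an error.
    """
    if isinstance(series, pd.DataFrame):
        series = series.set_index(pd.DatetimeIndex(series["date"]))["count"]
    series = series.sort_index()
    calendar = pd.DatetimeIndex(series.index)
    if calendar.has_duplicates:
        raise FeatureError("series has duplicate dates; pass a single cell")

    cov = covariates.reindex(calendar.union(covariates.index)).sort_index()
    for col in WW_FEATURES:
        if col in cov.columns:
            cov[col] = cov[col].ffill()
    cov = cov.reindex(calendar)
    needed = [c for c in MET_FEATURES + WW_FEATURES if c in covariates.columns]
    if cov[needed].isna().any().any():
        bad = cov[needed].isna().any()
        raise FeatureError(f"covariate gaps after forward-fill in {list(bad[bad].index)}")

    X = pd.DataFrame(index=calendar)
    dow = calendar.dayofweek
    for i in range(7):
        X[f"dow_{i}"] = (dow == i).astype(int)
    # season index: consecutive windows separated by >30 days start a new season
    gaps = np.diff(calendar.values).astype("timedelta64[D]").astype(int)
    season = np.concatenate([[0], np.cumsum(gaps > 30)])
    X["season_index"] = season
    day_of_season = np.zeros(len(calendar), dtype=int)
    for s in np.unique(season):
        mask = season == s
        start = calendar[mask][0]
        day_of_season[mask] = (calendar[mask] - start).days
    X["day_of_season"] = day_of_season
    X["day_of_year"] = calendar.dayofyear
    if holidays is None:
        holidays = default_holidays(sorted(set(calendar.year)))
    X["holiday"] = np.array([d.date() in holidays for d in calendar], dtype=int)
    for col in needed:
        X[col] = cov[col].to_numpy()

    pre_mask = calendar < pd.Timestamp(event_date)
    y = series.to_numpy(dtype=float)
    return FeatureSplit(
        pre_X=X.loc[pre_mask],
        pre_y=y[pre_mask],
        post_X=X.loc[~pre_mask],
        post_y=y[~pre_mask] if (~pre_mask).any() else None,
        pre_dates=calendar[pre_mask],
        post_dates=calendar[~pre_mask],
    )


# ---------------------------------------------------------------------------
# cross-validation folds
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CVConfig:
    """Rolling-origin cross-validation layout within the pre-period."""

    n_folds: int = 5
    min_train_days: int = 150

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.min_train_days < 1:
            raise ValueError("min_train_days must be >= 1")


def rolling_origin_folds(
    n_dates: int, config: CVConfig
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Index folds: validation blocks tile the tail of the pre-period.

    Each fold trains on every date before its validation block, so every
    validation date is strictly later than all of its training dates. The
    ``n_folds`` equal-length blocks cover the last
    ``n_folds * floor((n - min_train) / n_folds)`` days.
    """
    if n_dates < config.min_train_days + config.n_folds:
        raise FoldError(
            f"{n_dates} pre-period days cannot support {config.n_folds} folds "
            f"with min_train_days={config.min_train_days}"
        )
    val_len = (n_dates - config.min_train_days) // config.n_folds
    first_val = n_dates - config.n_folds * val_len
    folds = []
    for i in range(config.n_folds):
        v0 = first_val + i * val_len
        folds.append((np.arange(0, v0), np.arange(v0, v0 + val_len)))
    return folds


# ---------------------------------------------------------------------------
# learners
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LearnerSpec:
    """Hyperparameter grid for the hybrid learner.

    ``base_grid`` entries configure the harmonic base (``n_harmonics``);
    ``residual_grid`` entries configure the boosted residual component
    (``max_depth``, ``n_estimators``, ``learning_rate``) or are ``None`` to
    disable it (pure linear harmonic regression). The full candidate grid is
    the Cartesian product.
    """

    base_grid: tuple[dict, ...] = ({"n_harmonics": 2},)
    residual_grid: tuple[dict | None, ...] = (
        {
            "max_depth": 2,
            "n_estimators": 100,
            "learning_rate": 0.05,
            "min_child_weight": 20,
            "reg_lambda": 10,
        },
    )

    def candidates(self) -> list[tuple[dict, dict | None]]:
        grid = list(itertools.product(self.base_grid, self.residual_grid))
        if not grid:
            raise FitError("empty hyperparameter grid")
        return grid


def default_learner_spec() -> LearnerSpec:
    """Moderate grid: harmonic order and trend terms for the base, crossed
    with no boosting, gentle boosting, and deeper boosting."""
    return LearnerSpec(
        base_grid=(
            {"n_harmonics": 1},
            {"n_harmonics": 2},
            {"n_harmonics": 3},
            {"n_harmonics": 2, "trend": True, "season_intercepts": True},
        ),
        residual_grid=(
            None,
            {"max_depth": 2, "n_estimators": 100, "learning_rate": 0.05,
             "min_child_weight": 20, "reg_lambda": 10},
            {"max_depth": 3, "n_estimators": 150, "learning_rate": 0.05,
             "min_child_weight": 10, "reg_lambda": 5},
        ),
    )


class HarmonicBase:
    """OLS on weekday dummies, annual harmonics of day-of-year, and the
    holiday flag; optionally a within-season linear trend and per-season
    intercepts.

    The trend and season-intercept terms are off by default: both are
    estimated from the head of each season and extrapolated to its tail,
    which inflates prediction variance exactly where the post-event window
    sits, so they are offered as grid options for rolling-origin CV to keep
    or reject rather than hard-wired."""

    def __init__(self, n_harmonics: int = 2, trend: bool = False, season_intercepts: bool = False):
        self.n_harmonics = int(n_harmonics)
        self.trend = bool(trend)
        self.season_intercepts = bool(season_intercepts)
        self.coef_: np.ndarray | None = None
        self._season_levels: np.ndarray | None = None

    def _design(self, X: pd.DataFrame) -> np.ndarray:
        cols = [np.ones(len(X))]
        for i in range(1, 7):  # Monday is the reference level
            cols.append(X[f"dow_{i}"].to_numpy(dtype=float))
        theta = 2.0 * np.pi * X["day_of_year"].to_numpy(dtype=float) / 365.25
        for k in range(1, self.n_harmonics + 1):
            cols.append(np.sin(k * theta))
            cols.append(np.cos(k * theta))
        if self.trend:
            cols.append(X["day_of_season"].to_numpy(dtype=float) / 100.0)
        if self.season_intercepts:
            for level in self._season_levels[1:]:  # first season is the reference
                cols.append((X["season_index"].to_numpy() == level).astype(float))
        cols.append(X["holiday"].to_numpy(dtype=float))
        return np.column_stack(cols)

    def fit(self, X: pd.DataFrame, y: np.ndarray) -> "HarmonicBase":
        self._season_levels = np.unique(X["season_index"].to_numpy())
        D = self._design(X)
        self.coef_, *_ = np.linalg.lstsq(D, y, rcond=None)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if self.coef_ is None:
            raise FitError("base component not fitted")
        return self._design(X) @ self.coef_


def _make_booster(params: dict, seed: int):
    import xgboost as xgb

    return xgb.XGBRegressor(
        max_depth=int(params.get("max_depth", 2)),
        n_estimators=int(params.get("n_estimators", 100)),
        learning_rate=float(params.get("learning_rate", 0.05)),
        min_child_weight=float(params.get("min_child_weight", 20)),
        reg_lambda=float(params.get("reg_lambda", 10)),
        objective="reg:squarederror",
        tree_method="hist",
        base_score=0.0,
        n_jobs=1,
        random_state=int(seed) % (2**31),
        verbosity=0,
    )


@dataclass
class _HybridModel:
    base: HarmonicBase
    booster: object | None
    feature_columns: tuple[str, ...]

    def predict_raw(self, X: pd.DataFrame) -> np.ndarray:
        pred = self.base.predict(X)
        if self.booster is not None:
            pred = pred + self.booster.predict(X[list(self.feature_columns)].to_numpy(dtype=float))
        return pred


def _fit_hybrid(
    X: pd.DataFrame,
    y: np.ndarray,
    base_params: dict,
    resid_params: dict | None,
    seed: int,
) -> _HybridModel:
    base = HarmonicBase(**base_params).fit(X, y)
    booster = None
    feature_columns = tuple(X.columns)
    if resid_params is not None:
        resid = y - base.predict(X)
        booster = _make_booster(resid_params, seed)
        booster.fit(X[list(feature_columns)].to_numpy(dtype=float), resid)
    return _HybridModel(base=base, booster=booster, feature_columns=feature_columns)


# ---------------------------------------------------------------------------
# fitting and prediction
# ---------------------------------------------------------------------------


@dataclass
class CounterfactualFit:
    """Trained stage-1 learner with its CV diagnostics and residuals.

    ``residuals`` are in-sample (observed minus full-pre-period refit);
    ``oof_residuals`` are the honest rolling-origin validation residuals of
    the selected candidate, at positions ``oof_index`` of the pre-period.
    Relative residuals (residual / fitted) are carried for scale-aware
    uncertainty propagation downstream.
    """

    selected_base: dict
    selected_residual: dict | None
    fold_rmse: list[float]
    cv_table: list[dict]
    fitted: np.ndarray
    residuals: np.ndarray
    relative_residuals: np.ndarray
    oof_index: np.ndarray
    oof_residuals: np.ndarray
    oof_relative_residuals: np.ndarray
    pre_dates: pd.DatetimeIndex
    feature_columns: tuple[str, ...]
    model: _HybridModel = field(repr=False)

    @property
    def selected_rmse(self) -> float:
        return float(np.mean(self.fold_rmse))


def fit_counterfactual(
    pre_X: pd.DataFrame,
    pre_y: np.ndarray,
    spec: LearnerSpec | None = None,
    cv: CVConfig | None = None,
    seed: int = 0,
) -> CounterfactualFit:
    """Grid-search the hybrid learner by rolling-origin CV and refit the winner.

    For every candidate the mean RMSE over validation folds is computed; the
    argmin candidate (ties broken by grid order) is refit on the full
    pre-period. Deterministic given the seed. Raises :class:`FitError` for an
    all-zero outcome and :class:`FoldError` when the pre-period is too short.
    """
    spec = spec or LearnerSpec()
    cv = cv or CVConfig()
    pre_y = np.asarray(pre_y, dtype=float)
    if len(pre_X) == 0:
        raise FitError("empty pre-period: event date precedes all data")
    if len(pre_X) != len(pre_y):
        raise FitError("pre_X and pre_y lengths differ")
    if np.allclose(pre_y, 0.0):
        raise FitError("outcome is constant zero over the pre-period")

    folds = rolling_origin_folds(len(pre_X), cv)
    candidates = spec.candidates()

    cv_table: list[dict] = []
    per_candidate_fold_rmse: list[list[float]] = []
    per_candidate_val_pred: list[list[np.ndarray]] = []
    for base_params, resid_params in candidates:
        fold_rmse = []
        val_preds = []
        for train_idx, val_idx in folds:
            model = _fit_hybrid(
                pre_X.iloc[train_idx], pre_y[train_idx], base_params, resid_params, seed
            )
            pred = model.predict_raw(pre_X.iloc[val_idx])
            val_preds.append(pred)
            fold_rmse.append(float(np.sqrt(np.mean((pre_y[val_idx] - pred) ** 2))))
        per_candidate_fold_rmse.append(fold_rmse)
        per_candidate_val_pred.append(val_preds)
        cv_table.append(
            {
                "base": dict(base_params),
                "residual": dict(resid_params) if resid_params is not None else None,
                "mean_rmse": float(np.mean(fold_rmse)),
            }
        )

    best = int(np.argmin([row["mean_rmse"] for row in cv_table]))
    base_params, resid_params = candidates[best]

    # honest residuals: the winning candidate's fold validation errors
    oof_index_parts, oof_resid_parts, oof_rel_parts = [], [], []
    for (train_idx, val_idx), pred in zip(folds, per_candidate_val_pred[best]):
        resid = pre_y[val_idx] - pred
        oof_index_parts.append(val_idx)
        oof_resid_parts.append(resid)
        denom = np.where(np.abs(pred) > 1e-12, pred, np.nan)
        oof_rel_parts.append(resid / denom)

    final = _fit_hybrid(pre_X, pre_y, base_params, resid_params, seed)
    fitted = final.predict_raw(pre_X)
    residuals = pre_y - fitted
    denom = np.where(np.abs(fitted) > 1e-12, fitted, np.nan)
    relative = residuals / denom

    pre_dates = (
        pd.DatetimeIndex(pre_X.index)
        if isinstance(pre_X.index, pd.DatetimeIndex)
        else pd.DatetimeIndex([])
    )
    return CounterfactualFit(
        selected_base=dict(base_params),
        selected_residual=dict(resid_params) if resid_params is not None else None,
        fold_rmse=per_candidate_fold_rmse[best],
        cv_table=cv_table,
        fitted=fitted,
        residuals=residuals,
        relative_residuals=np.nan_to_num(relative, nan=0.0),
        oof_index=np.concatenate(oof_index_parts),
        oof_residuals=np.concatenate(oof_resid_parts),
        oof_relative_residuals=np.nan_to_num(np.concatenate(oof_rel_parts), nan=0.0),
        pre_dates=pre_dates,
        feature_columns=tuple(pre_X.columns),
        model=final,
    )


@dataclass
class PredictionResult:
    """Counterfactual post-period predictions; negatives clipped to 0 and flagged."""

    values: np.ndarray
    raw: np.ndarray
    clipped: np.ndarray
    dates: pd.DatetimeIndex


def predict_counterfactual(
    fit: CounterfactualFit, post_X: pd.DataFrame
) -> PredictionResult:
    """Predict nonnegative counterfactual counts for the post-period.

    Uses only post-period *features*, never post-period outcomes. Raw
    predictions below zero are clipped to zero and flagged.
    """
    if len(post_X) == 0:
        raise PredictionError("post-period feature matrix is empty")
    if tuple(post_X.columns) != fit.feature_columns:
        raise PredictionError(
            f"feature schema mismatch: fitted on {fit.feature_columns}, got {tuple(post_X.columns)}"
        )
    raw = fit.model.predict_raw(post_X)
    values = np.clip(raw, 0.0, None)
    dates = (
        pd.DatetimeIndex(post_X.index)
        if isinstance(post_X.index, pd.DatetimeIndex)
        else pd.DatetimeIndex([])
    )
    return PredictionResult(values=values, raw=raw, clipped=raw < 0.0, dates=dates)


# ---------------------------------------------------------------------------
# conveniences
# ---------------------------------------------------------------------------


@dataclass
class CellResult:
    """Stage-1 output for one stratum x modality x cause cell."""

    cell: tuple[str, str, str]
    fit: CounterfactualFit
    prediction: PredictionResult
    observed_post: np.ndarray
    post_dates: pd.DatetimeIndex


def fit_cell(
    visits: pd.DataFrame,
    covariates: pd.DataFrame,
    event_date: date,
    cell: tuple[str, str, str],
    spec: LearnerSpec | None = None,
    cv: CVConfig | None = None,
    seed: int = 0,
    holidays: set[date] | None = None,
) -> CellResult:
    """Filter the tidy visit cube to one cell, fit stage 1, and predict."""
    stratum, modality, cause = cell
    sel = visits[
        (visits["stratum"] == stratum)
        & (visits["modality"] == modality)
        & (visits["cause"] == cause)
    ]
    if sel.empty:
        raise FitError(f"no rows for cell {cell}")
    split = build_features(sel[["date", "count"]], covariates, event_date, holidays)
    fit = fit_counterfactual(split.pre_X, split.pre_y, spec, cv, seed)
    pred = predict_counterfactual(fit, split.post_X)
    observed_post = split.post_y if split.post_y is not None else np.array([])
    return CellResult(
        cell=cell,
        fit=fit,
        prediction=pred,
        observed_post=observed_post,
        post_dates=split.post_dates,
    )


def fit_summary_json(fit: CounterfactualFit, prediction: PredictionResult | None = None) -> str:
    """Deterministic JSON summary of a fit (hyperparameters, CV diagnostics,
    fitted values, residuals, and optionally predictions). Contains no
    timestamps, so identical fits serialize to identical bytes."""
    payload = {
        "selected_base": fit.selected_base,
        "selected_residual": fit.selected_residual,
        "fold_rmse": [float(v) for v in fit.fold_rmse],
        "cv_table": fit.cv_table,
        "pre_dates": [str(d.date()) for d in fit.pre_dates],
        "fitted": [float(v) for v in fit.fitted],
        "residuals": [float(v) for v in fit.residuals],
        "oof_index": [int(i) for i in fit.oof_index],
        "oof_residuals": [float(v) for v in fit.oof_residuals],
    }
    if prediction is not None:
        payload["prediction_dates"] = [str(d.date()) for d in prediction.dates]
        payload["predicted"] = [float(v) for v in prediction.values]
        payload["clipped"] = [bool(b) for b in prediction.clipped]
    return json.dumps(payload, sort_keys=True, indent=1)
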