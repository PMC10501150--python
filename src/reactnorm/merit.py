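"""Predicting the merit of unobserved environments from weather and soil.

Daily April-October weather is aggregated per month with a per-variable
function (totals for precipitation and photosynthetically active radiation,
maxima for maximum temperature and wind speed, minima for minimum
temperature and dew point, means otherwise) and combined with soil variables
at three depth intervals into one feature row per environment.  A Random
Forest regressor, tuned by 10-fold cross-validation over a small grid of
candidate-predictors-per-split and tree-count values, maps the features to
the scaled environment merit theta; predictions are clipped to [-1, 1]
because the polynomial basis is only valid on the training gradient's
domain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

__all__ = ["CovariateFeatureTable", "MeritModel", "build_features",
           "fit_merit_model", "predict_merit"]

_MONTHS = [4, 5, 6, 7, 8, 9, 10]

# aggregation function per weather variable
_TOTAL = {"PRECTOTCORR", "ALLSKY_SFC_PAR_TOT"}
_MAX = {"T2M_MAX", "WS2M"}
_MIN = {"T2M_MIN", "T2MDEW"}
_WEATHER_VARS = ["ALLSKY_SFC_PAR_TOT", "T2MWET", "QV2M", "RH2M", "T2M_MAX",
                 "PS", "T2MDEW", "WS2M", "T2M_MIN", "T2M", "PRECTOTCORR"]
_SOIL_VARS = ["Sand", "Silt", "Clay", "SOC", "Nitrogen"]
_SOIL_DEPTHS = ["0-5", "5-15", "15-30"]


def _agg_fun(var: str):
    if var in _TOTAL:
        return "sum"
    if var in _MAX:
        return "max"
    if var in _MIN:
        return "min"
    return "mean"


def feature_columns() -> list:
    cols = [f"{v}_{m:02d}" for v in _WEATHER_VARS for m in _MONTHS]
    cols += [f"{v}_{d}" for v in _SOIL_VARS for d in _SOIL_DEPTHS]
    return cols


@dataclass
class CovariateFeatureTable:
    """One feature row per environment (92 columns when complete)."""

    table: pd.DataFrame                  # index env_id
    dropped_envs: list = field(default_factory=list)

    @property
    def env_ids(self) -> list:
        return list(self.table.index)


def build_features(weather: pd.DataFrame, soil: pd.DataFrame,
                   max_missing_frac: float = 0.2) -> CovariateFeatureTable:
    """Aggregate daily weather and layered soil into per-environment rows.

    Weather needs columns env_id, date and the 11 variables; soil needs
    env_id, depth_cm and the 5 variables.  Months without any day of data
    yield missing features; environments with more than
    ``max_missing_frac`` of their features missing are dropped, and the
    remaining missing cells are imputed with the column median.
    """
    w = weather.copy()
    w["month"] = pd.to_datetime(w["date"]).dt.month
    w = w[w["month"].isin(_MONTHS)]
    env_ids = sorted(set(weather["env_id"]) | set(soil["env_id"]))
    out = pd.DataFrame(index=pd.Index(env_ids, name="env_id"),
                       columns=feature_columns(), dtype=float)

    for var in _WEATHER_VARS:
        if var not in w.columns:
            continue
        agg = (w.groupby(["env_id", "month"])[var]
               .agg(_agg_fun(var)).unstack("month"))
        for m in _MONTHS:
            if m in agg.columns:
                out.loc[agg.index, f"{var}_{m:02d}"] = agg[m]

    s = soil.copy()
    s["depth_cm"] = s["depth_cm"].astype(str)
    for var in _SOIL_VARS:
        if var not in s.columns:
            continue
        agg = s.groupby(["env_id", "depth_cm"])[var].mean().unstack()
        for d in _SOIL_DEPTHS:
            if d in agg.columns:
                out.loc[agg.index, f"{var}_{d}"] = agg[d]

    miss_frac = out.isna().mean(axis=1)
    dropped = list(out.index[miss_frac > max_missing_frac])
    if dropped:
        warnings.warn(f"environments dropped for missing features: {dropped}")
    out = out.loc[miss_frac <= max_missing_frac]
    out = out.fillna(out.median()).fillna(0.0)   # all-NaN columns -> 0
    return CovariateFeatureTable(table=out, dropped_envs=dropped)


@dataclass
class MeritModel:
    """Tuned Random Forest mapping environment features to theta."""

    model: RandomForestRegressor
    feature_names: list
    best_params: dict
    cv_results: pd.DataFrame
    cv_rmse: float
    cv_correlation: float
    train_medians: pd.Series
    theta_range: tuple
    beta_range: tuple | None = None


def _mtry_grid(p: int) -> list:
    cands = {max(1, p // 3), max(1, int(np.sqrt(p))), max(1, round(p / 2))}
    return sorted(cands)


def fit_merit_model(features: pd.DataFrame, theta: pd.Series, seed: int = 0,
                    n_folds: int = 10, n_trees_grid=(250, 500, 1000),
                    mtry_grid=None, beta_range=None) -> MeritModel:
    """Tune and fit the Random Forest merit model.

    The grid spans candidate-predictors-per-split values {p/3, sqrt(p), p/2}
    and the supplied tree counts; the pair minimizing ``n_folds``-fold
    cross-validated RMSE is refit on all training environments.  With fewer
    environments than folds the fold count is reduced with a warning.
    """
    if isinstance(features, CovariateFeatureTable):
        features = features.table
    X = features.copy()
    y = pd.Series(theta).reindex(X.index)
    if y.isna().any():
        missing = list(y.index[y.isna()])
        raise ValueError(f"no theta for environments: {missing}")
    if len(X) < 8:
        raise ValueError("need at least 8 training environments")
    medians = X.median()
    X = X.fillna(medians)
    p = X.shape[1]
    mtry_grid = mtry_grid or _mtry_grid(p)

    if len(X) < n_folds:
        warnings.warn(f"only {len(X)} environments; reducing folds "
                      f"from {n_folds} to {len(X)}")
        n_folds = len(X)
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    Xv, yv = X.to_numpy(), y.to_numpy(dtype=float)

    rows = []
    best = None
    for mtry in mtry_grid:
        for nt in n_trees_grid:
            pred = np.empty(len(yv))
            for tr, te in kf.split(Xv):
                rf = RandomForestRegressor(
                    n_estimators=nt, max_features=mtry, random_state=seed,
                    n_jobs=1)
                rf.fit(Xv[tr], yv[tr])
                pred[te] = rf.predict(Xv[te])
            rmse = float(np.sqrt(np.mean((pred - yv) ** 2)))
            corr = (float(np.corrcoef(pred, yv)[0, 1])
                    if np.std(pred) > 0 and np.std(yv) > 0 else 0.0)
            rows.append({"mtry": mtry, "n_trees": nt, "rmse": rmse,
                         "corr": corr})
            if best is None or rmse < best["rmse"]:
                best = rows[-1]
    final = RandomForestRegressor(n_estimators=best["n_trees"],
                                  max_features=best["mtry"],
                                  random_state=seed, n_jobs=1)
    final.fit(Xv, yv)
    return MeritModel(
        model=final, feature_names=list(X.columns),
        best_params={"mtry": best["mtry"], "n_trees": best["n_trees"]},
        cv_results=pd.DataFrame(rows), cv_rmse=best["rmse"],
        cv_correlation=best["corr"], train_medians=medians,
        theta_range=(float(np.min(yv)), float(np.max(yv))),
        beta_range=beta_range,
    )


def predict_merit(model: MeritModel, features: pd.DataFrame
                  ) -> pd.DataFrame:
    """Predict theta for new environments; raw values clipped to [-1, 1]."""
    if isinstance(features, CovariateFeatureTable):
        features = features.table
    missing = [c for c in model.feature_names if c not in features.columns]
    if missing:
        raise ValueError(f"feature schema mismatch; missing columns: "
                         f"{missing[:5]}{'...' if len(missing) > 5 else ''}")
    X = features[model.feature_names].copy()
    X = X.fillna(model.train_medians)
    raw = model.model.predict(X.to_numpy())
    clipped = np.clip(raw, -1.0, 1.0)
    return pd.DataFrame({"theta_raw": raw, "theta": clipped,
                         "clipped": raw != clipped},
                        index=features.index)
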