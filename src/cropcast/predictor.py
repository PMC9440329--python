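"""Stages 4 and 5 — district yield predictions and area-weighted regional
aggregation with uncertainty bands and validation metrics.

Hindcasts fit with the target year's yield censored; forecasts (years beyond
the yield record) use all observed years.  Regional values are growing-area
weighted means over the districts with available predictions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import t as student_t

from ._ols import FIT_MARGIN, fit_regression

__all__ = [
    "PredictionRecord",
    "ValidationMetrics",
    "predict_district",
    "aggregate",
    "validation_metrics",
    "uncertainty_interval",
    "build_aggregate_series",
]


@dataclass
class PredictionRecord:
    district: str
    target_year: int
    predicted: float
    mode: str  # "hindcast" | "forecast"
    combo: tuple[str, ...]


@dataclass
class ValidationMetrics:
    """Out-of-sample explained variance and error of a predicted series."""

    r2_val: float  # 1 - SSE/SST (may be negative)
    rmse: float
    r2_pearson: float  # squared Pearson correlation, secondary
    n_years: int


def predict_district(
    district: str,
    target_year: int,
    features: Sequence[str],
    yields: pd.Series,
    district_features: pd.DataFrame,
    mode: str = "hindcast",
    min_years: int = 17,
) -> PredictionRecord | None:
    """Predict one district-year from its selected feature combination.

    ``hindcast`` censors the target year's yield from the fit; ``forecast``
    fits on every observed year.  Returns ``None`` when the target year's
    feature values are missing or too few years remain to fit.
    """
    if mode not in ("hindcast", "forecast"):
        raise ValueError(f"unknown mode {mode!r}")
    features = list(features)
    target_x = district_features.reindex([target_year])[features]
    if target_x.isna().to_numpy().any():
        return None
    obs = yields.dropna()
    if mode == "hindcast":
        obs = obs[obs.index != target_year]
    feats = district_features.reindex(obs.index)[features]
    ok = feats.notna().all(axis=1) if features else pd.Series(True, index=obs.index)
    years = obs.index[ok.to_numpy()]
    if len(years) < max(min_years, len(features) + FIT_MARGIN):
        return None
    fit = fit_regression(
        np.asarray(years, dtype=float),
        obs.loc[years].to_numpy(),
        feats.loc[years].to_numpy(dtype=float) if features else None,
    )
    if fit.degenerate:
        return None
    pred = fit.predict(
        np.asarray([target_year], dtype=float),
        target_x.to_numpy(dtype=float).reshape(1, -1),
    )[0]
    return PredictionRecord(
        district=district,
        target_year=target_year,
        predicted=float(pred),
        mode=mode,
        combo=tuple(features),
    )


def aggregate(
    values: Mapping[str, float], weights: pd.Series, districts: Sequence[str] | None = None
) -> float:
    """Area-weighted mean over the districts with available values; weights
    are renormalised over those districts.  NaN when nothing is available."""
    items = [
        (d, v)
        for d, v in values.items()
        if np.isfinite(v) and d in weights.index and weights.loc[d] > 0
        and (districts is None or d in set(districts))
    ]
    if not items:
        return float("nan")
    w = np.asarray([weights.loc[d] for d, _ in items], dtype=float)
    v = np.asarray([v for _, v in items], dtype=float)
    return float((w * v).sum() / w.sum())


def validation_metrics(
    observed: pd.Series, predicted: pd.Series, min_years: int = 3
) -> ValidationMetrics:
    """R²_val = 1 - SSE/SST about the observed mean, plus RMSE and squared
    Pearson r, on the years where both series are present."""
    joined = pd.concat([observed, predicted], axis=1, join="inner").dropna()
    n = len(joined)
    if n < min_years:
        raise ValueError(f"need at least {min_years} paired years, got {n}")
    o = joined.iloc[:, 0].to_numpy(dtype=float)
    p = joined.iloc[:, 1].to_numpy(dtype=float)
    sse = float(np.sum((o - p) ** 2))
    sst = float(np.sum((o - o.mean()) ** 2))
    rmse = math.sqrt(sse / n)
    r2_val = 1.0 - sse / sst if sst > 0 else float("nan")
    if sst > 0 and np.std(p) > 0:
        r = float(np.corrcoef(o, p)[0, 1])
        r2_pearson = r * r
    else:
        r2_pearson = float("nan")
    return ValidationMetrics(r2_val=r2_val, rmse=rmse, r2_pearson=r2_pearson, n_years=n)


def uncertainty_interval(
    errors: Sequence[float], mode: str = "hindcast", level: float = 0.95
) -> tuple[float, float]:
    """(centre offset, half width) of the uncertainty band from a sample of
    past prediction errors.

    Hindcast bands are centred on the prediction and extend 1.96 sample
    standard deviations (95% coverage under a Gaussian error model).  The
    forecast band is centred on the mean past error and slightly wider,
    using the Student-t quantile inflated by sqrt(1 + 1/n).
    """
    e = np.asarray([x for x in errors if np.isfinite(x)], dtype=float)
    n = len(e)
    if n < 3:
        raise ValueError(f"need at least 3 errors, got {n}")
    sd = float(e.std(ddof=1))
    alpha = 1.0 - level
    if mode == "hindcast":
        z = 1.96 if level == 0.95 else float(student_t.ppf(1 - alpha / 2, np.inf))
        return 0.0, z * sd
    if mode == "forecast":
        tq = float(student_t.ppf(1 - alpha / 2, n - 1))
        return float(e.mean()), tq * sd * math.sqrt(1.0 + 1.0 / n)
    raise ValueError(f"unknown mode {mode!r}")


def build_aggregate_series(
    district_predictions: Mapping[int, Mapping[str, float]],
    yields: pd.DataFrame,
    weights: pd.Series,
    region_map: pd.Series | None = None,
    forecast_years: Sequence[int] = (),
) -> dict[str, pd.DataFrame]:
    """Regional observed/predicted series with uncertainty bands and metrics.

    *district_predictions* maps target year -> {district: predicted}.  Every
    region from *region_map* is aggregated directly from its districts; the
    pseudo-region ``"ALL"`` covers every district (no double weighting
    through intermediate levels).  Band half-widths come from the region's
    own hindcast errors.
    """
    regions: dict[str, list[str]] = {}
    all_districts = sorted(
        {d for preds in district_predictions.values() for d in preds}
    )
    if region_map is not None:
        for d, r in region_map.items():
            regions.setdefault(str(r), []).append(d)
    regions["ALL"] = all_districts

    out: dict[str, pd.DataFrame] = {}
    years = sorted(district_predictions)
    for region, dists in regions.items():
        rows = []
        for yr in years:
            preds = district_predictions[yr]
            pred = aggregate(preds, weights, dists)
            if yr in yields.columns:
                obs_vals = {
                    d: yields.at[d, yr]
                    for d in dists
                    if d in yields.index and np.isfinite(yields.at[d, yr])
                }
                obs = aggregate(obs_vals, weights, dists)
            else:
                obs = float("nan")
            rows.append({"year": yr, "observed": obs, "predicted": pred})
        df = pd.DataFrame(rows).set_index("year")
        errors = (df["predicted"] - df["observed"]).dropna()
        lo = pd.Series(np.nan, index=df.index)
        hi = pd.Series(np.nan, index=df.index)
        if len(errors) >= 3:
            for yr in df.index:
                mode = "forecast" if yr in set(forecast_years) else "hindcast"
                errs = errors
                if len(errs) < 3 or not np.isfinite(df.at[yr, "predicted"]):
                    continue
                centre, half = uncertainty_interval(errs, mode=mode)
                mid = df.at[yr, "predicted"] - (centre if mode == "forecast" else 0.0)
                lo.at[yr] = mid - half
                hi.at[yr] = mid + half
        df["lo"] = lo
        df["hi"] = hi
        out[region] = df
    return out
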