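"""In-situ calibration of raw sensor PM2.5 against regulatory stations.

Hours in which a participant's sensor was outdoors (per the context labels)
are paired with the nearest regulatory station, provided the station is
within a cut-off distance of the hour's mean outdoor position and reports
that hour. A linear mixed model — reference ~ raw + RH + temperature with a
per-participant random intercept, fitted by REML — maps raw sensor readings
to reference concentrations; the cut-off is chosen by scanning a grid and
keeping the distance that maximises the model's R². Calibrated
concentrations use the fixed effects only, so they generalise to hours and
participants without collocation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from pmexposure.config import CalibrationParams
from pmexposure.geo import LocalProjection


class CalibrationError(ValueError):
    pass


@dataclass
class CalibrationFit:
    coef: dict[str, float]  # intercept, raw, and covariate fixed effects
    re_var: float  # per-participant random-intercept variance
    resid_var: float
    r2: float  # squared Pearson correlation, fitted vs reference
    rmse: float
    cutoff_km: float
    n_pairs: int
    n_participants: int
    ols_fallback: bool = False
    covariates: tuple[str, ...] = ("rh", "temp")

    def predict(self, stream: pd.DataFrame, raw_col: str = "pm25") -> np.ndarray:
        """Fixed-effects prediction for minute records."""
        pred = self.coef["intercept"] + self.coef["raw"] * stream[raw_col].to_numpy()
        colmap = {"rh": "rh_pct", "temp": "temp_c"}
        for cov in self.covariates:
            pred = pred + self.coef.get(cov, 0.0) * stream[colmap.get(cov, cov)].to_numpy()
        return pred

    def to_json(self) -> str:
        return json.dumps(
            {
                "coef": self.coef,
                "re_var": self.re_var,
                "resid_var": self.resid_var,
                "r2": self.r2,
                "rmse": self.rmse,
                "cutoff_km": self.cutoff_km,
                "n_pairs": self.n_pairs,
                "n_participants": self.n_participants,
                "ols_fallback": self.ols_fallback,
                "covariates": list(self.covariates),
            },
            indent=2,
        )


def build_pairs(
    labels: pd.DataFrame,
    stream: pd.DataFrame,
    stations: pd.DataFrame,
    projection: LocalProjection,
    cutoff_km: float,
    min_outdoor_minutes: int = 30,
) -> pd.DataFrame:
    """Hourly collocation pairs from outdoor-labelled minutes.

    For each (participant, UTC hour) with at least ``min_outdoor_minutes``
    outdoor minutes, the hourly means of raw PM2.5, RH, temperature, and
    position are paired with the nearest station if it is within
    ``cutoff_km`` and reports that hour.
    """
    if stations.empty:
        raise CalibrationError("no regulatory stations available")
    outdoor = labels.loc[~labels["indoor"], ["participant_id", "timestamp_utc"]]
    merged = outdoor.merge(stream, on=["participant_id", "timestamp_utc"], how="inner")
    merged = merged.dropna(subset=["lat", "lon"])
    if merged.empty:
        return pd.DataFrame()
    merged["hour"] = pd.DatetimeIndex(merged["timestamp_utc"]).floor("h")
    x, y = projection.to_xy(merged["lon"].to_numpy(), merged["lat"].to_numpy())
    merged["x"], merged["y"] = x, y
    agg = (
        merged.groupby(["participant_id", "hour"], observed=True)
        .agg(
            n_minutes=("pm25", "size"),
            raw_pm25=("pm25", "mean"),
            rh=("rh_pct", "mean"),
            temp=("temp_c", "mean"),
            x=("x", "mean"),
            y=("y", "mean"),
        )
        .reset_index()
    )
    agg = agg[agg["n_minutes"] >= min_outdoor_minutes]
    if agg.empty:
        return pd.DataFrame()

    sites = stations.drop_duplicates("station_id")[["station_id", "lon", "lat"]]
    sx, sy = projection.to_xy(sites["lon"].to_numpy(), sites["lat"].to_numpy())
    d = np.hypot(
        agg["x"].to_numpy()[:, None] - sx[None, :],
        agg["y"].to_numpy()[:, None] - sy[None, :],
    )
    nearest = np.argmin(d, axis=1)
    agg["station_id"] = sites["station_id"].to_numpy()[nearest]
    agg["distance_m"] = d[np.arange(len(agg)), nearest]
    agg = agg[agg["distance_m"] <= cutoff_km * 1000.0]

    st = stations.rename(columns={"timestamp_utc": "hour", "pm25": "station_pm25"})
    pairs = agg.merge(st[["station_id", "hour", "station_pm25"]], on=["station_id", "hour"])
    return pairs.reset_index(drop=True)


def fit_calibration(
    pairs: pd.DataFrame,
    covariates: tuple[str, ...] = ("rh", "temp"),
    min_pairs: int = 50,
    cutoff_km: float = float("nan"),
) -> CalibrationFit:
    """REML mixed-model fit of reference on raw sensor hourly means."""
    if len(pairs) < min_pairs:
        raise CalibrationError(f"only {len(pairs)} pairs; need >= {min_pairs}")
    cols = ["raw_pm25"] + list(covariates)
    X = sm.add_constant(pairs[cols].to_numpy(), has_constant="add")
    yref = pairs["station_pm25"].to_numpy()
    names = ["intercept", "raw"] + list(covariates)
    res = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md = sm.MixedLM(yref, X, groups=pairs["participant_id"].to_numpy())
            res = md.fit(reml=True)
        if not res.converged:
            res = None
    except Exception:  # noqa: BLE001 - any optimisation failure falls back
        res = None
    ols_fallback = res is None
    if ols_fallback:
        warnings.warn("singular mixed-model fit; falling back to OLS", stacklevel=2)
        ols = sm.OLS(yref, X).fit()
        coef = dict(zip(names, np.asarray(ols.params)))
        fitted = np.asarray(ols.fittedvalues)
        re_var, resid_var = 0.0, float(ols.mse_resid)
    else:
        coef = dict(zip(names, np.asarray(res.fe_params)))
        fitted = np.asarray(res.fittedvalues)
        re_var, resid_var = float(np.asarray(res.cov_re)[0, 0]), float(res.scale)

    resid = yref - fitted
    rmse = float(np.sqrt(np.mean(resid**2)))
    if np.std(fitted) > 0 and np.std(yref) > 0:
        r2 = float(np.corrcoef(fitted, yref)[0, 1] ** 2)
    else:
        r2 = 0.0
    return CalibrationFit(
        coef=coef,
        re_var=re_var,
        resid_var=resid_var,
        r2=r2,
        rmse=rmse,
        cutoff_km=float(cutoff_km),
        n_pairs=int(len(pairs)),
        n_participants=int(pairs["participant_id"].nunique()),
        ols_fallback=ols_fallback,
        covariates=tuple(covariates),
    )


def scan_cutoffs(
    labels: pd.DataFrame,
    stream: pd.DataFrame,
    stations: pd.DataFrame,
    projection: LocalProjection,
    params: CalibrationParams | None = None,
) -> tuple[pd.DataFrame, CalibrationFit]:
    """Fit the calibration at each cut-off; keep the R²-maximising one.

    Ties select the smallest cut-off. The full per-cutoff diagnostic table
    is returned regardless of where the maximum falls.
    """
    params = params or CalibrationParams()
    rows = []
    fits: dict[float, CalibrationFit] = {}
    for cutoff in sorted(params.cutoff_grid_km):
        pairs = build_pairs(
            labels, stream, stations, projection, cutoff, params.min_outdoor_minutes
        )
        if len(pairs) < params.min_pairs:
            rows.append({"cutoff_km": cutoff, "n_pairs": len(pairs), "r2": np.nan,
                         "rmse": np.nan})
            continue
        fit = fit_calibration(pairs, tuple(params.covariates), params.min_pairs, cutoff)
        fits[cutoff] = fit
        rows.append({"cutoff_km": cutoff, "n_pairs": fit.n_pairs, "r2": fit.r2,
                     "rmse": fit.rmse})
    table = pd.DataFrame(rows)
    if not fits:
        raise CalibrationError("no cut-off produced enough collocation pairs")
    best = max(sorted(fits), key=lambda c: (fits[c].r2, -c))
    return table, fits[best]


def apply_calibration(
    fit: CalibrationFit, stream: pd.DataFrame, raw_col: str = "pm25"
) -> tuple[pd.DataFrame, int]:
    """Replace minute PM2.5 by the fixed-effects prediction, floored at 0."""
    out = stream.copy()
    pred = fit.predict(stream, raw_col=raw_col)
    n_floored = int((pred < 0).sum())
    out["pm25_calibrated"] = np.maximum(pred, 0.0)
    return out, n_floored
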