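"""Exposure summaries, dose apportionment, time budgets, and IDW comparison.

Exposure concentration is the minute-level calibrated PM2.5 (ug/m3);
exposure dose is cumulative inhaled mass (ug), i.e. concentration x
breathing rate x time. Dose proportions are therefore invariant to the
(constant) breathing rate. The home-based alternative reconstructs hourly
outdoor concentrations at the home coordinate by inverse-distance-weighted
interpolation of the station network, for comparison with the personal
series at both minute and hour scales.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from pmexposure.geo import LocalProjection

_PCTS = (2.5, 25, 50, 75, 97.5)


def _summary_row(v: np.ndarray) -> dict:
    # linear interpolation between order statistics (numpy default rule)
    pct = np.percentile(v, _PCTS)
    return {
        "n": int(len(v)),
        "mean": float(v.mean()),
        "sd": float(v.std(ddof=1)) if len(v) > 1 else 0.0,
        "p2.5": pct[0],
        "p25": pct[1],
        "p50": pct[2],
        "p75": pct[3],
        "p97.5": pct[4],
        "min": float(v.min()),
        "max": float(v.max()),
    }


def summarize(
    df: pd.DataFrame, value_col: str = "pm25_calibrated", group_by: str | list[str] | None = None
) -> pd.DataFrame:
    """Mean, sd, percentile, and range summary per group (empty groups omitted)."""
    if group_by is None:
        return pd.DataFrame([_summary_row(df[value_col].to_numpy())])
    group_by = [group_by] if isinstance(group_by, str) else list(group_by)
    missing = [g for g in group_by if g not in df.columns]
    if missing:
        raise KeyError(f"unknown grouping key(s): {missing}")
    rows = []
    for key, sub in df.groupby(group_by, sort=True, observed=True):
        key = key if isinstance(key, tuple) else (key,)
        row = dict(zip(group_by, key))
        row.update(_summary_row(sub[value_col].to_numpy()))
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class DoseBreakdown:
    by_microenv: pd.DataFrame  # microenv, minutes, mean_conc, dose_ug, proportion
    by_indoor: pd.DataFrame  # indoor, minutes, mean_conc, dose_ug, proportion
    total_dose_ug: float
    breathing_rate: float


def dose_apportion(
    labeled: pd.DataFrame,
    value_col: str = "pm25_calibrated",
    breathing_rate: float = 0.012,
) -> DoseBreakdown:
    """Apportion cumulative inhaled dose across microenvironments.

    ``labeled`` needs ``microenv``, ``indoor``, and the concentration
    column; each row is one minute, so dose per row is conc x rate x 1 min.
    """
    conc = labeled[value_col].to_numpy()
    total = float(conc.sum() * breathing_rate)
    if total <= 0:
        raise ValueError("zero total dose; proportions are undefined")

    def _table(key: str) -> pd.DataFrame:
        g = labeled.groupby(key, sort=True, observed=True)[value_col]
        out = pd.DataFrame(
            {
                "minutes": g.size(),
                "mean_conc": g.mean(),
                "dose_ug": g.sum() * breathing_rate,
            }
        ).reset_index()
        out["proportion"] = out["dose_ug"] / total
        return out

    return DoseBreakdown(
        by_microenv=_table("microenv"),
        by_indoor=_table("indoor"),
        total_dose_ug=total,
        breathing_rate=breathing_rate,
    )


def time_budget(labels: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Time fractions per microenvironment and for indoor/outdoor."""
    n = len(labels)
    if n == 0:
        return (
            pd.DataFrame(columns=["microenv", "minutes", "fraction"]),
            pd.DataFrame(columns=["indoor", "minutes", "fraction"]),
        )
    me = labels.groupby("microenv", sort=True, observed=True).size().rename("minutes").reset_index()
    me["fraction"] = me["minutes"] / n
    io = labels.groupby("indoor", sort=True, observed=True).size().rename("minutes").reset_index()
    io["fraction"] = io["minutes"] / n
    return me, io


def idw_home(
    stations: pd.DataFrame,
    home_lonlat: tuple[float, float],
    projection: LocalProjection,
    power: float = 2.0,
    max_radius_km: float = 50.0,
) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Hourly IDW interpolation of the station network at a home coordinate.

    Weights are proportional to distance^(-power) over in-radius stations
    reporting the hour and sum to one; a station at the home coordinate
    returns its own series. Returns (series, station weights, hours with no
    in-radius station).
    """
    sites = stations.drop_duplicates("station_id")[["station_id", "lon", "lat"]].reset_index(
        drop=True
    )
    if sites.empty:
        raise ValueError("no stations supplied")
    hx, hy = projection.to_xy(home_lonlat[0], home_lonlat[1])
    sx, sy = projection.to_xy(sites["lon"].to_numpy(), sites["lat"].to_numpy())
    dist = np.hypot(sx - hx, sy - hy)
    in_radius = dist <= max_radius_km * 1000.0

    wide = stations.pivot_table(
        index="timestamp_utc", columns="station_id", values="pm25", aggfunc="first"
    )
    wide = wide.reindex(columns=sites["station_id"])
    vals = wide.to_numpy()

    zero = dist < 1e-9
    if zero.any():
        j = int(np.argmax(zero))
        series = vals[:, j]
        weights = pd.DataFrame(
            {"station_id": sites["station_id"], "distance_m": dist,
             "weight": np.where(zero, 1.0, 0.0)[: len(sites)]}
        )
        n_missing = int(np.isnan(series).sum())
        out = pd.DataFrame({"timestamp_utc": wide.index, "pm25_idw": series})
        return out, weights, n_missing

    with np.errstate(divide="ignore"):
        w = np.where(in_radius, dist ** (-power), 0.0)
    have = ~np.isnan(vals)
    wmat = np.where(have, w[None, :], 0.0)
    denom = wmat.sum(axis=1)
    n_missing = int((denom == 0).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        series = np.where(denom > 0, np.nansum(wmat * vals, axis=1) / denom, np.nan)
    weights = pd.DataFrame(
        {"station_id": sites["station_id"], "distance_m": dist,
         "weight": np.where(denom.max() > 0, w / max(w.sum(), 1e-300), 0.0)}
    )
    out = pd.DataFrame({"timestamp_utc": wide.index, "pm25_idw": series})
    return out, weights, n_missing


def compare_personal_home(
    personal: pd.DataFrame,
    home: pd.DataFrame,
    value_col: str = "pm25_calibrated",
) -> dict:
    """Personal-vs-home comparison: Pearson r at two scales plus P/O ratios.

    ``home`` carries (participant_id, timestamp_utc hour, pm25_idw). Each
    personal minute is matched to its hour's home value (minute scale);
    hourly means of the personal series give the hour scale. The P/O ratio
    is per participant: mean personal exposure over mean home-based
    exposure across the monitoring window.
    """
    p = personal[["participant_id", "timestamp_utc", value_col]].copy()
    p["hour"] = pd.DatetimeIndex(p["timestamp_utc"]).floor("h")
    h = home.rename(columns={"timestamp_utc": "hour"})[
        ["participant_id", "hour", "pm25_idw"]
    ]
    m = p.merge(h, on=["participant_id", "hour"], how="inner").dropna(
        subset=[value_col, "pm25_idw"]
    )
    if len(m) < 2:
        raise ValueError("fewer than 2 overlapping personal/home observations")

    def _pearson(a: np.ndarray, b: np.ndarray):
        if np.std(a) == 0 or np.std(b) == 0:
            return float("nan")
        return float(np.corrcoef(a, b)[0, 1])

    r_minute = _pearson(m[value_col].to_numpy(), m["pm25_idw"].to_numpy())
    hourly = (
        m.groupby(["participant_id", "hour"], observed=True)
        .agg(personal=(value_col, "mean"), home=("pm25_idw", "first"))
        .reset_index()
    )
    r_hour = _pearson(hourly["personal"].to_numpy(), hourly["home"].to_numpy())

    po = (
        m.groupby("participant_id", observed=True)
        .apply(
            lambda g: g[value_col].mean() / g["pm25_idw"].mean()
            if g["pm25_idw"].mean() > 0
            else np.nan,
            include_groups=False,
        )
        .dropna()
    )
    q25, q50, q75 = (np.percentile(po, [25, 50, 75]) if len(po) else (np.nan,) * 3)
    return {
        "pearson_r_minute": r_minute,
        "pearson_r_hour": r_hour,
        "po_median": float(q50),
        "po_iqr": (float(q25), float(q75)),
        "n_minutes": int(len(m)),
        "n_participants": int(m["participant_id"].nunique()),
        "constant_home": bool(np.std(m["pm25_idw"].to_numpy()) == 0),
    }
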