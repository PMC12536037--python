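"""Design-row cohorts drawn from a known linear mixed model.

For recovery and coverage studies of the inference stage, rows are drawn
directly from the generative model the fitter assumes: a treatment-coded
fixed-effect structure (microenvironment, indoor x background, season,
hour, demographics) plus a Gaussian participant random intercept and
Gaussian residual, with every true coefficient known by name. This isolates
estimator calibration from trajectory- and calibration-stage error.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Defaults for the effects the cohort carries; anything absent is zero.
DEFAULT_TRUE_COEFS = {
    "intercept": 5.0,
    "indoor": 0.5,
    "season[winter]": 0.45,
    "hour[16-19]": 2.6,
    "idw": 0.279,
    "indoor:idw": -0.168,
}

_HOUR_BINS = {6: ["0-3", "4-7", "8-11", "12-15", "16-19", "20-23"]}

_LANDUSE_P = {
    "residential": 0.56,
    "public_facilities": 0.09,
    "commercial": 0.07,
    "office": 0.08,
    "park_open_space": 0.05,
    "industrial": 0.02,
    "other": 0.05,
    "vehicle": 0.08,
}
_DEMO_P = {
    "age_group": (["0-29", "30-39", "40-49", "50-59", "60+"], [0.13, 0.51, 0.09, 0.21, 0.06]),
    "sex": (["female", "male"], [0.79, 0.21]),
    "marital": (["unmarried", "married"], [0.41, 0.59]),
    "race": (["non-white", "white"], [0.06, 0.94]),
    "edu": (["lt_ba", "ba", "gt_ba"], [0.21, 0.44, 0.35]),
    "income": (["low", "high"], [0.36, 0.64]),
}
_SEASONS = ["spring", "summer", "autumn", "winter"]


def _balanced_categorical(rng, levels, probs, n: int) -> np.ndarray:
    """Composition-matched assignment: every level appears at least once."""
    probs = np.asarray(probs, dtype=float)
    counts = np.maximum(1, np.round(probs / probs.sum() * n).astype(int))
    while counts.sum() > n:
        counts[int(np.argmax(counts))] -= 1
    while counts.sum() < n:
        counts[int(np.argmin(counts / probs))] += 1
    out = np.repeat(np.array(levels, dtype=object), counts)
    return out[rng.permutation(n)]


def simulate_collocation_pairs(
    seed: int,
    n_pairs: int = 2000,
    slope: float = 0.5,
    intercept: float = 2.0,
    noise_sd: float = 0.3,
    re_sd: float = 0.2,
    n_participants: int = 20,
) -> pd.DataFrame:
    """Hourly collocation pairs with a known sensor distortion.

    Reference = slope * raw + intercept, plus a participant random
    intercept and Gaussian noise; RH and temperature are drawn but carry no
    effect, so their fitted coefficients should be null.
    """
    rng = np.random.default_rng(seed)
    pid = rng.integers(0, n_participants, n_pairs)
    b = rng.normal(0.0, re_sd, n_participants)
    raw = rng.uniform(2.0, 30.0, n_pairs)
    ref = slope * raw + intercept + b[pid] + rng.normal(0.0, noise_sd, n_pairs)
    return pd.DataFrame(
        {
            "participant_id": [f"P{i:04d}" for i in pid],
            "hour": pd.Timestamp("2019-01-01", tz="UTC") + pd.to_timedelta(
                np.arange(n_pairs), unit="h"
            ),
            "n_minutes": 60,
            "raw_pm25": raw,
            "rh": rng.uniform(30.0, 90.0, n_pairs),
            "temp": rng.uniform(0.0, 25.0, n_pairs),
            "station_id": "S000",
            "distance_m": 400.0,
            "station_pm25": ref,
        }
    )


def simulate_design(
    seed: int,
    n_participants: int = 40,
    n_days: int = 3,
    minute_step: int = 5,
    true_coefs: dict[str, float] | None = None,
    re_sd: float = 1.0,
    resid_sd: float = 2.0,
    hour_bins: int | None = 6,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Simulate design rows with known effects; returns (rows, true coefs).

    ``hour_bins=6`` collapses the 24-hour factor to 4-hour bins (named
    ``0-3`` ... ``20-23``); ``None`` keeps 24 hourly levels named ``0``-``23``.
    Participant-level draws (season of monitoring, demographics, random
    intercept) are constant within participant; row-level draws
    (microenvironment, indoor, background) vary by minute.
    """
    truth = dict(DEFAULT_TRUE_COEFS if true_coefs is None else true_coefs)
    rng = np.random.default_rng(seed)
    rows_per_day = 1440 // minute_step
    n_rows = n_participants * n_days * rows_per_day

    pids = np.repeat([f"P{i:04d}" for i in range(n_participants)], n_days * rows_per_day)
    minute = np.tile(np.arange(n_days * rows_per_day) * minute_step, n_participants)
    hour = (minute // 60) % 24
    if hour_bins is not None:
        bins = _HOUR_BINS[hour_bins]
        hour_label = np.array(bins, dtype=object)[hour // (24 // hour_bins)]
    else:
        hour_label = hour.astype(str).astype(object)

    season_p = _balanced_categorical(rng, _SEASONS, [0.25] * 4, n_participants)
    b_p = rng.normal(0.0, re_sd, n_participants)
    demo_p = {
        f: _balanced_categorical(rng, levels, p, n_participants)
        for f, (levels, p) in _DEMO_P.items()
    }

    rep = n_days * rows_per_day
    df = pd.DataFrame(
        {
            "studyid": pids,
            "hour": hour_label,
            "season": np.repeat(season_p, rep),
            "landuse": rng.choice(
                np.array(list(_LANDUSE_P), dtype=object), size=n_rows,
                p=np.array(list(_LANDUSE_P.values())),
            ),
        }
    )
    indoor = rng.random(n_rows) < 0.85
    indoor[df["landuse"] == "vehicle"] = True
    indoor[df["landuse"] == "park_open_space"] = False
    df["indoor"] = indoor
    df["idw"] = np.clip(
        6.0 + 2.0 * np.cos(2 * np.pi * (hour - 19) / 24.0) + rng.normal(0.0, 1.5, n_rows),
        0.5,
        None,
    )
    for f, vals in demo_p.items():
        df[f] = np.repeat(vals, rep)

    from pmexposure.design import build_design

    df["y"] = 0.0
    design = build_design(df, response="y", demographics="full", hour_col="hour",
                          check_rank=False)
    beta = np.array([truth.get(name, 0.0) for name in design.names])
    mean = design.X @ beta
    df["y"] = mean + np.repeat(b_p, rep) + rng.normal(0.0, resid_sd, n_rows)
    return df, truth
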