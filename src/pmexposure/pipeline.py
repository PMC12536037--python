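"""End-to-end driver chaining the processing stages.

Pre-processing -> context identification -> in-situ calibration -> exposure
assessment -> inference, with per-stage accounting and deterministic table
outputs. Every stage also remains callable on its own; this module only
sequences them and assembles the shared intermediate frames (e.g. the
minute-level design rows that join calibrated exposures, context labels,
home background, and demographics).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from pmexposure import calibrate as cal
from pmexposure import context as ctx
from pmexposure import exposure as expo
from pmexposure import io as pio
from pmexposure import preprocess as pre
from pmexposure.config import RunConfig
from pmexposure.design import CANONICAL_LEVELS, DEMOGRAPHIC_FACTORS
from pmexposure.mixedmodel import FitResult, fit_model, variance_components_icc


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineResult:
    accounts: pd.DataFrame
    labels: pd.DataFrame
    valid_labels: pd.DataFrame
    context_diags: dict
    cutoff_table: pd.DataFrame
    calibration: cal.CalibrationFit
    stream: pd.DataFrame  # calibrated minute records
    summary_overall: pd.DataFrame
    summary_microenv: pd.DataFrame
    dose: expo.DoseBreakdown
    time_microenv: pd.DataFrame
    time_indoor: pd.DataFrame
    home_series: pd.DataFrame
    comparison: dict
    design_rows: pd.DataFrame
    fit: Optional[FitResult] = None
    icc: Optional[float] = None
    extras: dict = field(default_factory=dict)


def local_season(ts: pd.DatetimeIndex, timezone: str) -> np.ndarray:
    """Meteorological season from the local month."""
    month = ts.tz_convert(timezone).month.to_numpy()
    out = np.empty(len(month), dtype=object)
    out[np.isin(month, (3, 4, 5))] = "spring"
    out[np.isin(month, (6, 7, 8))] = "summer"
    out[np.isin(month, (9, 10, 11))] = "autumn"
    out[np.isin(month, (12, 1, 2))] = "winter"
    return out


def build_home_series(
    stations: pd.DataFrame,
    homes: pd.DataFrame,
    projection,
    power: float,
    max_radius_km: float,
    stream: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Hourly IDW series at each home, cropped to that participant's window.

    When ``stream`` is given, each participant's series covers only the
    hours they were actually monitored.
    """
    windows = None
    if stream is not None:
        ts = pd.DatetimeIndex(stream["timestamp_utc"]).floor("h")
        grp = pd.DataFrame({"participant_id": stream["participant_id"], "hour": ts})
        windows = grp.groupby("participant_id", observed=True)["hour"].agg(["min", "max"])
    frames = []
    for _, row in homes.iterrows():
        series, _, _ = expo.idw_home(
            stations, (row["lon"], row["lat"]), projection, power, max_radius_km
        )
        if windows is not None and row["participant_id"] in windows.index:
            lo, hi = windows.loc[row["participant_id"]]
            hours = pd.DatetimeIndex(series["timestamp_utc"])
            series = series[(hours >= lo) & (hours <= hi)]
        series = series.copy()
        series.insert(0, "participant_id", row["participant_id"])
        frames.append(series)
    return pd.concat(frames, ignore_index=True)


def assemble_design_rows(
    labeled_stream: pd.DataFrame,
    home_series: pd.DataFrame,
    demographics: pd.DataFrame,
    timezone: str,
) -> pd.DataFrame:
    """Minute-level model rows: exposure ~ context + background + time + person."""
    df = labeled_stream.copy()
    ts = pd.DatetimeIndex(df["timestamp_utc"])
    df["hour"] = ts.tz_convert(timezone).hour.astype(str)
    df["season"] = local_season(ts, timezone)
    df["hour_key"] = ts.floor("h")
    home = home_series.rename(columns={"timestamp_utc": "hour_key", "pm25_idw": "idw"})
    df = df.merge(home, on=["participant_id", "hour_key"], how="left")
    df = df.dropna(subset=["idw"])
    df = df.merge(demographics, on="participant_id", how="left")
    df = df.rename(columns={"microenv": "landuse", "participant_id": "studyid"})
    df["y"] = df["pm25_calibrated"]
    keep = ["studyid", "y", "landuse", "indoor", "idw", "season", "hour"] + [
        f for f in DEMOGRAPHIC_FACTORS if f in df.columns
    ]
    return df[keep + ["timestamp_utc"]]


def estimable_demographics(rows: pd.DataFrame) -> tuple[str, ...]:
    """Demographic factors with at least two observed levels in the rows."""
    return tuple(
        f for f in DEMOGRAPHIC_FACTORS
        if f in rows.columns and rows[f].nunique() >= 2
    )


def run_pipeline(
    stream: pd.DataFrame,
    stations: pd.DataFrame,
    area: ctx.StudyArea,
    homes: pd.DataFrame,
    demographics: pd.DataFrame,
    cfg: RunConfig | None = None,
    fit_inference: bool = True,
    ci_coefs=None,
) -> PipelineResult:
    cfg = cfg or RunConfig()
    try:
        clean, accounts, _ = pre.preprocess(stream)
    except Exception as exc:  # noqa: BLE001
        raise StageError("preprocess", exc) from exc

    try:
        labels, diags = ctx.identify_context(clean, area, cfg.context)
        valid_labels, dropped_days = ctx.filter_valid_days(
            labels, cfg.context.min_valid_hours, cfg.context.timezone
        )
        diags["dropped_participant_days"] = int(len(dropped_days))
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("context", exc) from exc

    try:
        cutoff_table, fit = cal.scan_cutoffs(
            labels, clean, stations, area.projection, cfg.calibration
        )
        calibrated, n_floored = cal.apply_calibration(fit, clean)
        diags["calibration_floored"] = n_floored
    except Exception as exc:  # noqa: BLE001
        raise StageError("calibrate", exc) from exc

    try:
        labeled = valid_labels.merge(
            calibrated[["participant_id", "timestamp_utc", "pm25_calibrated"]],
            on=["participant_id", "timestamp_utc"],
            how="inner",
        )
        summary_overall = expo.summarize(calibrated, "pm25_calibrated")
        summary_microenv = expo.summarize(labeled, "pm25_calibrated", "microenv")
        dose = expo.dose_apportion(labeled, breathing_rate=cfg.exposure.breathing_rate)
        time_me, time_io = expo.time_budget(valid_labels)
        home_series = build_home_series(
            stations, homes, area.projection, cfg.exposure.idw_power,
            cfg.exposure.idw_max_radius_km, stream=calibrated,
        )
        comparison = expo.compare_personal_home(calibrated, home_series)
    except Exception as exc:  # noqa: BLE001
        raise StageError("assess", exc) from exc

    fit_result = None
    icc = None
    design_rows = pd.DataFrame()
    if fit_inference:
        try:
            design_rows = assemble_design_rows(
                labeled, home_series, demographics, cfg.context.timezone
            )
            from pmexposure.design import DesignError

            demo = estimable_demographics(design_rows)
            try:
                fit_result = fit_model(
                    design_rows, demographics=demo, ci_coefs=ci_coefs
                )
            except DesignError:
                # small cohorts alias participant-level covariates; refit the
                # spatiotemporal model alone rather than failing the run
                fit_result = fit_model(
                    design_rows, demographics="none", ci_coefs=ci_coefs
                )
            icc, _ = variance_components_icc(design_rows)
        except Exception as exc:  # noqa: BLE001
            raise StageError("infer", exc) from exc

    return PipelineResult(
        accounts=pre.accounts_to_frame(accounts),
        labels=labels,
        valid_labels=valid_labels,
        context_diags=diags,
        cutoff_table=cutoff_table,
        calibration=fit,
        stream=calibrated,
        summary_overall=summary_overall,
        summary_microenv=summary_microenv,
        dose=dose,
        time_microenv=time_me,
        time_indoor=time_io,
        home_series=home_series,
        comparison=comparison,
        design_rows=design_rows,
        fit=fit_result,
        icc=icc,
    )


def write_outputs(result: PipelineResult, outdir) -> list[str]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = []

    def _w(name: str, df: pd.DataFrame) -> None:
        pio.write_table(df, outdir / name)
        files.append(name)

    _w("stage_accounts.csv", result.accounts)
    pio.write_labels(result.valid_labels, outdir / "labels.csv")
    files.append("labels.csv")
    _w("cutoff_table.csv", result.cutoff_table)
    (outdir / "calibration.json").write_text(result.calibration.to_json() + "\n")
    files.append("calibration.json")
    _w("summary_overall.csv", result.summary_overall)
    _w("summary_microenv.csv", result.summary_microenv)
    _w("dose_microenv.csv", result.dose.by_microenv)
    _w("dose_indoor.csv", result.dose.by_indoor)
    _w("time_microenv.csv", result.time_microenv)
    _w("time_indoor.csv", result.time_indoor)
    home = result.home_series.copy()
    home["timestamp_utc"] = pd.DatetimeIndex(home["timestamp_utc"]).strftime(
        "%Y-%m-%dT%H:%M:%SZ"
    )
    _w("home_idw.csv", home)
    comp = {k: v for k, v in result.comparison.items()}
    comp["po_iqr"] = list(comp["po_iqr"])
    (outdir / "comparison.json").write_text(json.dumps(comp, indent=2) + "\n")
    files.append("comparison.json")
    if result.fit is not None:
        (outdir / "fit.json").write_text(result.fit.to_json() + "\n")
        files.append("fit.json")
        _w("fit_table.csv", result.fit.table())
    (outdir / "context_diagnostics.json").write_text(
        json.dumps(result.context_diags, indent=2, sort_keys=True, default=int) + "\n"
    )
    files.append("context_diagnostics.json")
    return files
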