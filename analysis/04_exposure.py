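"""Exposure assessment: summaries, dose apportionment, home-based comparison.

Summarises calibrated exposure overall and per microenvironment, apportions
the inhaled dose across microenvironments and indoor/outdoor, reconstructs
home-address exposure by IDW interpolation of the station network, and
compares the two assessment approaches.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, SCRATCH, ensure_dirs, run_config

import pandas as pd

from pmexposure import io as pio
from pmexposure.context import StudyArea
from pmexposure.exposure import compare_personal_home, dose_apportion, summarize, time_budget
from pmexposure.pipeline import build_home_series


def main() -> None:
    ensure_dirs()
    cfg = run_config()
    calibrated = pio.read_stream(SCRATCH / "calibrated.csv").rename(
        columns={"pm25": "pm25_calibrated"}
    )
    labels = pio.read_labels(SCRATCH / "labels.csv")
    stations = pio.read_stations(SCRATCH / "stations.csv")
    homes = pd.read_csv(SCRATCH / "homes.csv", dtype={"participant_id": "string"})
    area = StudyArea.from_geojson(SCRATCH / "landuse.geojson",
                                  SCRATCH / "buildings.geojson",
                                  SCRATCH / "region.geojson")

    labeled = labels.merge(
        calibrated[["participant_id", "timestamp_utc", "pm25_calibrated"]],
        on=["participant_id", "timestamp_utc"],
    )
    overall = summarize(calibrated, "pm25_calibrated")
    by_env = summarize(labeled, "pm25_calibrated", "microenv")
    overall.to_csv(RESULTS / "summary_overall.csv", index=False)
    by_env.to_csv(RESULTS / "summary_microenv.csv", index=False)
    r = overall.iloc[0]
    print(f"overall exposure: {r['mean']:.1f} +/- {r['sd']:.1f} ug/m3 "
          f"(median {r['p50']:.1f}, n = {int(r['n']):,} minutes)")

    dose = dose_apportion(labeled, breathing_rate=cfg.exposure.breathing_rate)
    dose.by_microenv.to_csv(RESULTS / "dose_microenv.csv", index=False)
    dose.by_indoor.to_csv(RESULTS / "dose_indoor.csv", index=False)
    me, io_tab = time_budget(labels)
    me.to_csv(RESULTS / "time_microenv.csv", index=False)
    indoor_dose = dose.by_indoor.set_index("indoor")["proportion"].get(True, 0.0)
    res_dose = dose.by_microenv.set_index("microenv")["proportion"].get(
        "residential", 0.0)
    indoor_time = io_tab.set_index("indoor")["fraction"].get(True, 0.0)
    print(f"indoor: {100 * indoor_time:.0f} % of time, "
          f"{100 * indoor_dose:.0f} % of inhaled dose "
          f"(total dose {dose.total_dose_ug:.0f} ug over the week)")
    print(f"residential dose share: {100 * res_dose:.0f} %")

    home_series = build_home_series(stations, homes, area.projection,
                                    cfg.exposure.idw_power,
                                    cfg.exposure.idw_max_radius_km,
                                    stream=calibrated)
    home_series.to_csv(RESULTS / "home_idw.csv", index=False)
    comp = compare_personal_home(calibrated, home_series)
    comp["po_iqr"] = list(comp["po_iqr"])
    (RESULTS / "comparison.json").write_text(json.dumps(comp, indent=2) + "\n")
    print(f"personal vs home-IDW: r = {comp['pearson_r_minute']:.2f} (minute), "
          f"{comp['pearson_r_hour']:.2f} (hour); "
          f"P/O median {comp['po_median']:.2f} "
          f"(IQR {comp['po_iqr'][0]:.2f}-{comp['po_iqr'][1]:.2f})")


if __name__ == "__main__":
    main()
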