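"""In-situ calibration: cut-off scan and sensor-distortion recovery.

Pairs outdoor-labelled hours with the nearest station across a grid of
cut-off distances, keeps the R2-maximising cut-off, and applies the fitted
correction to every minute. The generator distorted the sensor with
reference = 0.5 * raw + 2.0 ug/m3, so the fitted slope should sit near 0.5.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, SCRATCH, ensure_dirs, run_config

from pmexposure import io as pio
from pmexposure.calibrate import apply_calibration, scan_cutoffs
from pmexposure.context import StudyArea
from pmexposure.preprocess import preprocess


def main() -> None:
    ensure_dirs()
    cfg = run_config()
    stream = pio.read_stream(SCRATCH / "personal.csv")
    clean, _, _ = preprocess(stream)
    labels = pio.read_labels(SCRATCH / "labels.csv")
    stations = pio.read_stations(SCRATCH / "stations.csv")
    area = StudyArea.from_geojson(SCRATCH / "landuse.geojson",
                                  SCRATCH / "buildings.geojson",
                                  SCRATCH / "region.geojson")

    table, fit = scan_cutoffs(labels, clean, stations, area.projection,
                              cfg.calibration)
    table.to_csv(RESULTS / "cutoff_table.csv", index=False)
    (RESULTS / "calibration.json").write_text(fit.to_json() + "\n")
    print(table.to_string(index=False))
    print(f"selected cut-off: {fit.cutoff_km} km "
          f"(R2 = {fit.r2:.3f}, RMSE = {fit.rmse:.2f} ug/m3, n = {fit.n_pairs})")
    print(f"fitted slope on raw = {fit.coef['raw']:.3f} "
          f"(generator truth 0.5); intercept = {fit.coef['intercept']:.2f}")

    calibrated, n_floored = apply_calibration(fit, clean)
    pio.write_stream(
        calibrated.drop(columns=["pm25"]).rename(columns={"pm25_calibrated": "pm25"}),
        SCRATCH / "calibrated.csv",
    )
    print(f"calibrated {len(calibrated):,} minutes ({n_floored} floored at 0)")


if __name__ == "__main__":
    main()
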