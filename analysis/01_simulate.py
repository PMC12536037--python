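"""Generate the synthetic monitoring study with full ground truth.

Emits the five-file bundle (personal 1-min stream, hourly stations,
land-use/building/region layers) plus demographics, home coordinates, and
the per-minute ground truth, under scratch/study/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import SCRATCH, ensure_dirs, run_config

from pmexposure.synthetic import generate_world, write_world


def main() -> None:
    ensure_dirs()
    cfg = run_config()
    world = generate_world(cfg.world)
    files = write_world(world, SCRATCH)
    indoor = world.truth["indoor"].mean()
    print(f"wrote {len(files)} files to {SCRATCH}")
    print(f"cohort: {cfg.world.n_participants} participants x {cfg.world.n_days} days "
          f"= {len(world.stream):,} minute records")
    print(f"ground-truth indoor time fraction: {indoor:.3f} "
          f"(target {cfg.world.indoor_target})")
    print(f"stations: {world.stations['station_id'].nunique()}; "
          f"true sensor distortion: reference = {cfg.world.sensor_slope} * raw "
          f"+ {cfg.world.sensor_intercept} ug/m3")


if __name__ == "__main__":
    main()
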