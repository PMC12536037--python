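"""Shared configuration for the numbered analysis scripts.

The scripts run a desk-scale synthetic study (10 participants, one week of
1-min monitoring) through the full pipeline. Bulky intermediates live under
scratch/ (regenerated on demand); the tables worth reading land in
results/.
"""

from pathlib import Path

from pmexposure.config import RunConfig, WorldConfig

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "study"
RESULTS = ROOT / "results" / "analysis"

SEED = 7


def run_config() -> RunConfig:
    cfg = RunConfig(seed=SEED)
    cfg.world = WorldConfig(seed=SEED, n_participants=10, n_days=7)
    cfg.calibration.min_pairs = 30
    return cfg


def ensure_dirs() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
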