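"""Record- and participant-level quality filters with stage accounting.

Two filters: drop records missing a timestamp, participant id, or any of
the nine pollution channels; then drop whole participants whose channels
are all-zero for more than 99% of their monitoring time (a dead sensor).
GPS missingness never drops a record here — non-GPS minutes still feed the
overall exposure assessment. Every stage logs how many records it removed
and what remains, with percentages always taken against the raw total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from pmexposure.io import POLLUTION_COLS


@dataclass
class StageAccount:
    stage: str
    dropped: int
    remaining: int
    raw_total: int
    detail: str = ""

    @property
    def dropped_pct(self) -> float:
        return 100.0 * self.dropped / self.raw_total if self.raw_total else 0.0

    @property
    def remaining_pct(self) -> float:
        return 100.0 * self.remaining / self.raw_total if self.raw_total else 0.0

    def render_dropped(self) -> str:
        """E.g. ``(N = 46,616, 0.9 %)``."""
        return f"(N = {self.dropped:,}, {self.dropped_pct:.1f} %)"


def accounts_to_frame(accounts: list[StageAccount]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "stage": [a.stage for a in accounts],
            "dropped": [a.dropped for a in accounts],
            "remaining": [a.remaining for a in accounts],
            "dropped_pct_of_raw": [round(a.dropped_pct, 1) for a in accounts],
            "remaining_pct_of_raw": [round(a.remaining_pct, 1) for a in accounts],
            "detail": [a.detail for a in accounts],
        }
    )


def drop_invalid_records(
    stream: pd.DataFrame, raw_total: int | None = None, missing_rule: str = "any"
) -> tuple[pd.DataFrame, StageAccount]:
    """Remove records with missing timestamp, id, or pollution data.

    ``missing_rule='any'`` (default) drops a record if any of the nine
    channels is missing; ``'all'`` only when every channel is missing.
    """
    if missing_rule not in {"any", "all"}:
        raise ValueError("missing_rule must be 'any' or 'all'")
    raw_total = raw_total if raw_total is not None else len(stream)
    ts = pd.to_datetime(stream["timestamp_utc"], utc=True, errors="coerce")
    bad_key = ts.isna() | stream["participant_id"].isna()
    poll_na = stream[POLLUTION_COLS].isna()
    bad_poll = poll_na.any(axis=1) if missing_rule == "any" else poll_na.all(axis=1)
    keep = ~(bad_key | bad_poll)
    out = stream.loc[keep]
    account = StageAccount(
        stage="drop_invalid_records",
        dropped=int((~keep).sum()),
        remaining=int(keep.sum()),
        raw_total=raw_total,
        detail=f"missing timestamp/id or pollution channel ({missing_rule})",
    )
    return out, account


def deduplicate(stream: pd.DataFrame, raw_total: int | None = None):
    """Keep the first record per (participant, timestamp); count duplicates."""
    raw_total = raw_total if raw_total is not None else len(stream)
    keep = ~stream.duplicated(subset=["participant_id", "timestamp_utc"], keep="first")
    out = stream.loc[keep]
    account = StageAccount(
        stage="deduplicate",
        dropped=int((~keep).sum()),
        remaining=int(keep.sum()),
        raw_total=raw_total,
        detail="duplicate (participant, timestamp) pairs",
    )
    return out, account


def drop_zero_participants(
    stream: pd.DataFrame, raw_total: int | None = None, zero_fraction: float = 0.99
) -> tuple[pd.DataFrame, StageAccount, list[str]]:
    """Drop participants whose records are all-zero over > ``zero_fraction``.

    A record counts as all-zero when every count and mass channel equals
    zero simultaneously. The threshold is strict (exceedance), so a
    participant at exactly 99.0% is retained.
    """
    raw_total = raw_total if raw_total is not None else len(stream)
    allzero = (stream[POLLUTION_COLS] == 0).all(axis=1)
    frac = allzero.groupby(stream["participant_id"], observed=True).mean()
    bad = set(frac.index[frac > zero_fraction])
    empty = set()  # participants present in the index but with zero records
    if bad:
        warnings.warn(
            f"dropping {len(bad)} participant(s) with >{zero_fraction:.0%} all-zero records",
            stacklevel=2,
        )
    keep = ~stream["participant_id"].isin(bad)
    out = stream.loc[keep]
    account = StageAccount(
        stage="drop_zero_participants",
        dropped=int((~keep).sum()),
        remaining=int(keep.sum()),
        raw_total=raw_total,
        detail=f"{len(bad)} participant(s) >{zero_fraction:.0%} all-zero channels",
    )
    return out, account, sorted(bad | empty)


def preprocess(
    stream: pd.DataFrame, missing_rule: str = "any", zero_fraction: float = 0.99
) -> tuple[pd.DataFrame, list[StageAccount], list[str]]:
    """Full pre-processing chain; accounting closes against the raw total."""
    raw_total = len(stream)
    out, acc1 = drop_invalid_records(stream, raw_total, missing_rule)
    out, acc2 = deduplicate(out, raw_total)
    out, acc3, dropped_ids = drop_zero_participants(out, raw_total, zero_fraction)
    return out, [acc1, acc2, acc3], dropped_ids
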