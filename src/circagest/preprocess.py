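"""Raw-record preprocessing: event filtering, sleep scoring, 5-min blocks,
hourly series and study-block assignment.

Conventions
-----------
* ZT0 = lights-on; dark phase = [ZT12, ZT24).
* Study blocks are half-open on the left boundary: block 1 = days
  [0.5, 6.5), block 2 = [6.5, 12.5), block 3 = [12.5, 17.5] (a termination
  day ends a block, so boundary days belong to the later block).
* Intake and activity are summed within 5-min blocks and reported hourly in
  per-hour units (the sum of the 12 blocks); wake fractions are averaged.
* An hour with any unrecorded 5-min slot is reported missing (NaN), never
  rescaled from the remaining slots.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FOOD_EVENT_MIN_G = 0.002  # intake events below this are excluded (strict <)
SLEEP_RUN_S = 40          # stillness runs of at least this length count as sleep
BLOCK_S = 300             # 5-min block length
SUM_BEHAVIOURS = ("food", "water", "activity")


def filter_food_events(records: pd.DataFrame) -> pd.DataFrame:
    """Drop food events with intake < 0.002 g (strict; the boundary is kept).

    Negative values of any behaviour are rejected with a logged warning.
    Non-food behaviours are untouched.
    """
    neg = records["value"] < 0
    if neg.any():
        logger.warning("rejecting %d records with negative values", int(neg.sum()))
        records = records[~neg]
    keep = (records["behaviour"] != "food") | (records["value"] >= FOOD_EVENT_MIN_G)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("excluded %d food events < %.3f g", n_drop, FOOD_EVENT_MIN_G)
    return records[keep].reset_index(drop=True)


def score_sleep(stillness: np.ndarray, block_s: int = BLOCK_S) -> np.ndarray:
    """Per-5-min asleep fraction from a 1-s stillness flag stream.

    A second counts as sleep iff it belongs to a contiguous stillness run of
    at least 40 s; runs qualify by their full length even when they straddle
    block boundaries.  The stream length must be a multiple of ``block_s``.
    Wakefulness is ``1 - asleep_fraction``.
    """
    stillness = np.asarray(stillness, dtype=bool)
    if stillness.size % block_s:
        raise ValueError("stillness stream length must be a multiple of the block length")
    if stillness.size == 0:
        return np.empty(0)
    # run-length encode
    edges = np.flatnonzero(np.diff(stillness.astype(np.int8))) + 1
    starts = np.concatenate([[0], edges])
    ends = np.concatenate([edges, [stillness.size]])
    asleep = np.zeros(stillness.size, dtype=bool)
    for s, e in zip(starts, ends):
        if stillness[s] and e - s >= SLEEP_RUN_S:
            asleep[s:e] = True
    return asleep.reshape(-1, block_s).mean(axis=1)


def to_five_min(records: pd.DataFrame, interval_s: Optional[int] = None) -> pd.DataFrame:
    """Aggregate raw records into 5-min blocks.

    Intake/activity values are summed; wake fractions averaged.  Records may
    arrive at any interval <= 300 s that divides 300; 300-s input passes
    through.  Duplicate (mouse, behaviour, block) entries raise.
    Returns columns mouse_id, group, day, zt_start, behaviour, value where
    ``day`` is the decimal day of the block start.
    """
    df = records.copy()
    if interval_s is None:
        # infer from the time step of the first mouse/behaviour stream
        g = df.sort_values("day").groupby(["mouse_id", "behaviour"])["day"]
        steps = g.diff().dropna()
        interval_s = int(round(steps[steps > 0].min() * 86400))
    if interval_s > BLOCK_S or BLOCK_S % interval_s:
        raise ValueError(f"sampling interval {interval_s}s must divide {BLOCK_S}s")
    per_block = BLOCK_S // interval_s
    step_day = BLOCK_S / 86400.0
    # tolerance well below the smallest sub-block offset (1/per_block >= 1/300)
    df["block_idx"] = np.floor(df["day"].to_numpy() / step_day + 1e-4).astype(np.int64)
    agg = (
        df.groupby(["mouse_id", "group", "behaviour", "block_idx"], observed=True, sort=False)
        .agg(value=("value", "sum"), n=("value", "size"))
        .reset_index()
    )
    if (agg["n"] > per_block).any():
        raise ValueError("duplicate records within a 5-min block")
    wake = agg["behaviour"] == "wake"
    agg.loc[wake, "value"] = agg.loc[wake, "value"] / agg.loc[wake, "n"]
    agg["day"] = agg["block_idx"] * step_day
    # exact ZT from the integer block index (12 blocks per hour)
    agg["zt_start"] = (agg["block_idx"] % 288) / 12.0
    return agg[["mouse_id", "group", "day", "zt_start", "behaviour", "value", "block_idx"]]


def assign_block(day) -> np.ndarray:
    """Study block for decimal day(s): [0.5,6.5) -> 1, [6.5,12.5) -> 2,
    [12.5,17.5] -> 3; anything else -> 0 (excluded, logged)."""
    day = np.asarray(day, dtype=float)
    out = np.zeros(day.shape, dtype=int)
    out[(day >= 0.5) & (day < 6.5)] = 1
    out[(day >= 6.5) & (day < 12.5)] = 2
    out[(day >= 12.5) & (day <= 17.5)] = 3
    n_out = int((out == 0).sum())
    if n_out:
        logger.info("excluded %d rows outside study days [0.5, 17.5]", n_out)
    return out


def hourly_series(blocks: pd.DataFrame) -> pd.DataFrame:
    """Per-mouse hourly series from the 5-min block table.

    An hour's value is the sum of its 12 blocks for intake/activity (per-hour
    units) and their mean for wake.  Slot coverage is judged across
    behaviours: a 5-min slot is covered if any behaviour recorded it, and
    behaviours with no event in a covered slot contribute zero (an excluded
    tiny food event is zero intake, not missing data).  Hours with fewer than
    12 covered slots are missing (NaN).

    Returns mouse_id, group, day (integer calendar day), zt_hour (0-23),
    behaviour, value, study_block, phase.
    """
    df = blocks.copy()
    if "block_idx" not in df.columns:
        df["block_idx"] = np.floor(df["day"].to_numpy() * 288 + 1e-4).astype(np.int64)
    hour_idx = df["block_idx"].to_numpy() // 12
    df["day_idx"] = hour_idx // 24
    df["zt_hour"] = (hour_idx % 24).astype(int)

    slots = df[["mouse_id", "group", "day", "day_idx", "zt_hour"]].drop_duplicates()
    coverage = (
        slots.groupby(["mouse_id", "group", "day_idx", "zt_hour"], sort=False)
        .size()
        .rename("n_slots")
        .reset_index()
    )
    behaviours = df["behaviour"].unique()
    # full grid: covered hours x behaviours
    grid = coverage.merge(pd.DataFrame({"behaviour": behaviours}), how="cross")
    sums = (
        df.groupby(["mouse_id", "group", "day_idx", "zt_hour", "behaviour"], sort=False)
        .agg(value=("value", "sum"), n=("value", "size"))
        .reset_index()
    )
    out = grid.merge(sums, on=["mouse_id", "group", "day_idx", "zt_hour", "behaviour"], how="left")
    out["value"] = out["value"].fillna(0.0)
    wake = out["behaviour"] == "wake"
    # wake is a mean over recorded slots; intake/activity are sums (zeros fill gaps)
    out.loc[wake, "value"] = out.loc[wake, "value"] / out.loc[wake, "n"]
    out.loc[out["n_slots"] < 12, "value"] = np.nan
    # a wake hour is missing unless all 12 wake slots were recorded
    out.loc[wake & (out["n"].fillna(0) < 12), "value"] = np.nan
    out = out.rename(columns={"day_idx": "day"})
    decimal_day = out["day"] + out["zt_hour"] / 24.0
    out["study_block"] = assign_block(decimal_day)
    out["phase"] = np.where(out["day"] < 0, "acclimation", "study")
    return out[["mouse_id", "group", "day", "zt_hour", "behaviour", "value", "study_block", "phase"]]


def _infer_interval(records: pd.DataFrame) -> int:
    g = records.sort_values("day").groupby(["mouse_id", "behaviour"])["day"]
    steps = g.diff().dropna()
    steps = steps[steps > 0]
    if steps.empty:
        return BLOCK_S
    return int(round(steps.min() * 86400))


def aggregate(records: pd.DataFrame, interval_s: Optional[int] = None) -> pd.DataFrame:
    """Full preprocessing chain: food-event filter -> 5-min blocks -> hourly.

    Input already at hourly resolution (3600 s) passes through unchanged
    (aggregation is idempotent on hourly data).
    """
    records = filter_food_events(records)
    if interval_s is None:
        interval_s = _infer_interval(records)
    if interval_s == 3600:
        out = records.copy()
        out["day"] = np.floor(np.round(out["day"], 9)).astype(np.int64)
        out["zt_hour"] = np.floor(out["zt_hour"]).astype(int)
        decimal_day = out["day"] + out["zt_hour"] / 24.0
        out["study_block"] = assign_block(decimal_day)
        out["phase"] = np.where(out["day"] < 0, "acclimation", "study")
        return out[["mouse_id", "group", "day", "zt_hour", "behaviour", "value", "study_block", "phase"]]
    return hourly_series(to_five_min(records, interval_s))
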