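"""Posterior peak detection and group comparison within circadian windows.

For every posterior draw of a fitted group x block curve we ask whether a
local maximum occurs inside each window of interest (an interior grid point
strictly above both neighbours; window-edge maxima do not count), and record
its time and amplitude (largest-amplitude maximum wins; ties go to the
earliest time).  Summaries per window x block report the share of draws with
a detected peak per group, peak time/amplitude posterior means with 2.5/97.5%
quantiles over the peak-bearing draws, and pregnant-minus-nonpregnant
differences computed per draw over draws where both groups show a peak.  A
difference is significant when its credible interval excludes zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .model import PosteriorCurves
from .profiles import WINDOWS

MIN_JOINT_FRACTION = 0.01


def significance(interval: Tuple[float, float]) -> bool:
    """True iff the credible interval excludes zero (strictly: lower > 0 or
    upper < 0; an endpoint at exactly zero counts as crossing)."""
    lo, hi = float(interval[0]), float(interval[1])
    if np.isnan(lo) or np.isnan(hi):
        raise ValueError("credible interval endpoints must be finite")
    return lo > 0.0 or hi < 0.0


def detect_peaks_draws(
    draws: np.ndarray, grid: np.ndarray, window: Tuple[float, float]
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised peak detection for a stack of curve draws.

    Parameters
    ----------
    draws : (n_draws, G) curve values on ``grid``
    grid : evaluation grid; must cover the window plus one point either side
    window : [lo, hi) on the unwrapped ZT axis

    Returns (present, time, amplitude) arrays of length n_draws (time and
    amplitude are NaN where no peak is present).
    """
    lo, hi = window
    if grid[0] >= lo or grid[-1] < hi:
        raise ValueError(f"grid does not cover window [{lo}, {hi}) with margins")
    inner = (grid >= lo) & (grid < hi)
    idx = np.flatnonzero(inner)
    v = draws[:, idx]
    left = draws[:, idx - 1]
    right = draws[:, idx + 1]
    is_max = (v > left) & (v > right)
    present = is_max.any(axis=1)
    # largest amplitude among local maxima; earliest time breaks ties
    masked = np.where(is_max, v, -np.inf)
    best = masked.argmax(axis=1)  # argmax returns the first of equal maxima
    time = np.where(present, grid[idx][best], np.nan)
    amp = np.where(present, v[np.arange(v.shape[0]), best], np.nan)
    return present, time, amp


@dataclass
class PeakSummary:
    """Tables-style summary of one window x block comparison."""

    window: str
    block: int
    presence: Dict[str, float]  # % of draws with a detected peak, per group
    stats: pd.DataFrame         # rows time/amplitude x group/difference
    note: Optional[str] = None


def _mean_ci(x: np.ndarray) -> Tuple[float, float, float]:
    return float(np.mean(x)), float(np.quantile(x, 0.025)), float(np.quantile(x, 0.975))


def summarise(
    curves: PosteriorCurves,
    block: int,
    window_id: str,
    force: bool = False,
) -> PeakSummary:
    """Summarise peak presence, timing and amplitude for one window x block.

    Group differences are conditional on joint presence within a draw; when
    fewer than 1% of draws have a peak in both groups the difference is
    reported as undefined.  Refuses non-converged fits unless ``force``.
    """
    if not curves.converged and not force:
        raise RuntimeError(
            f"{curves.behaviour} fit flagged non-converged (R-hat {curves.rhat_max:.3f}); "
            "pass force=True to summarise anyway"
        )
    window = WINDOWS[window_id]
    res = {}
    for group in ("nonpregnant", "pregnant"):
        d = curves.draws[(group, block)]
        present, time, amp = detect_peaks_draws(d, curves.zt_grid, window)
        assert np.all((time[present] >= window[0]) & (time[present] < window[1]))
        res[group] = (present, time, amp)

    presence = {g: 100.0 * res[g][0].mean() for g in res}
    rows = []
    for qty, k in (("time", 1), ("amplitude", 2)):
        for g in res:
            present = res[g][0]
            if present.any():
                m, lo, hi = _mean_ci(res[g][k][present])
            else:
                m = lo = hi = np.nan
            rows.append({"quantity": qty, "series": g, "mean": m, "lo2.5": lo, "hi97.5": hi,
                         "significant": np.nan})
    joint = res["nonpregnant"][0] & res["pregnant"][0]
    note = None
    if joint.mean() >= MIN_JOINT_FRACTION:
        for qty, k in (("time", 1), ("amplitude", 2)):
            diff = res["pregnant"][k][joint] - res["nonpregnant"][k][joint]
            m, lo, hi = _mean_ci(diff)
            rows.append({"quantity": qty, "series": "difference", "mean": m,
                         "lo2.5": lo, "hi97.5": hi, "significant": significance((lo, hi))})
    else:
        note = f"difference undefined: joint presence in {100 * joint.mean():.1f}% of draws (< 1%)"
        for qty in ("time", "amplitude"):
            rows.append({"quantity": qty, "series": "difference", "mean": np.nan,
                         "lo2.5": np.nan, "hi97.5": np.nan, "significant": np.nan})
    return PeakSummary(window_id, block, presence, pd.DataFrame(rows), note)


def peak_table(curves: PosteriorCurves, force: bool = False) -> pd.DataFrame:
    """Full Tables-1-to-4-shaped summary: one row per window x block with
    presence %, peak time/amplitude (mean [2.5%, 97.5%]) per group, and the
    pregnant-minus-nonpregnant differences with significance flags."""
    blocks = sorted({b for _, b in curves.draws})
    rows = []
    for window_id in WINDOWS:
        for block in blocks:
            s = summarise(curves, block, window_id, force=force)
            rec = {"behaviour": curves.behaviour, "window": window_id, "block": block,
                   "presence_nonpregnant_pct": s.presence["nonpregnant"],
                   "presence_pregnant_pct": s.presence["pregnant"], "note": s.note}
            for _, r in s.stats.iterrows():
                key = f"{r['quantity']}_{r['series']}"
                rec[f"{key}_mean"] = r["mean"]
                rec[f"{key}_lo"] = r["lo2.5"]
                rec[f"{key}_hi"] = r["hi97.5"]
                if r["series"] == "difference":
                    rec[f"{key}_significant"] = r["significant"]
            rows.append(rec)
    return pd.DataFrame(rows)
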