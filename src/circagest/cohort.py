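"""Synthetic metabolic-cage cohort generator.

Emits per-interval raw records (default 300 s) for each mouse over a 7-day
acclimation period (days -7..0) and a study period starting at day 0.5
(detection of mating) until the mouse's termination day (6.5, 12.5 or 17.5).
Intake and activity records are generated on the square-root scale --
``value = max(0, sqrt(mean/blocks_per_hour) + mouse_intercept + noise)**2`` --
and wakefulness as per-interval Beta fractions, so the downstream sqrt-scale
Gaussian and logit-scale beta models are well specified up to the smooth
ground-truth curve.

Raw records are written/read as CSV with the header
``mouse_id,group,day,zt_hour,behaviour,value`` where ``day`` is the decimal
study day (negative during acclimation) and ``zt_hour`` the decimal ZT of the
interval start.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, Optional

import numpy as np
import pandas as pd
import yaml

from .profiles import (
    WINDOWS,
    BehaviourProfileSpec,
    CohortConfig,
    PregnancyEffectSpec,
    default_effects,
    default_profiles,
    mean_curve,
)

RAW_COLUMNS = ["mouse_id", "group", "day", "zt_hour", "behaviour", "value"]


def _logit(p):
    return np.log(p / (1.0 - p))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def _blocks(config: CohortConfig, start_day: float, end_day: float) -> np.ndarray:
    """Decimal days of interval starts in [start_day, end_day)."""
    step = config.sampling_interval / 86400.0
    n = int(round((end_day - start_day) / step))
    return start_day + step * np.arange(n)


def generate_cohort(
    config: CohortConfig,
    profiles: Optional[Dict[str, BehaviourProfileSpec]] = None,
    effects: Optional[PregnancyEffectSpec] = None,
) -> pd.DataFrame:
    """Generate raw records for the whole cohort.

    Reproducibility contract: ``config.random_seed`` must be set; with a
    fixed seed the output is bit-identical.
    """
    if config.random_seed is None:
        raise ValueError("CohortConfig.random_seed must be set (reproducibility contract)")
    profiles = profiles if profiles is not None else default_profiles()
    effects = effects if effects is not None else default_effects()
    rng = np.random.default_rng(config.random_seed)
    per_hour = 3600 // config.sampling_interval

    mice = [("nonpregnant", i) for i in range(config.n_nonpregnant)] + [
        ("pregnant", i) for i in range(config.n_pregnant)
    ]
    frames = []
    for group, idx in mice:
        mouse_id = f"{'np' if group == 'nonpregnant' else 'pg'}{idx:02d}"
        term = config.termination_day(group, idx)
        days = np.concatenate(
            [
                _blocks(config, -float(config.acclimation_days), 0.0),
                _blocks(config, 0.5, min(term, config.study_days + 0.5)),
            ]
        )
        zt = (days * 24.0) % 24.0
        # mean curves are evaluated at interval midpoints
        zt_mid = ((days + config.sampling_interval / 172800.0) * 24.0) % 24.0
        study = days >= 0.5
        block = np.zeros(days.size, dtype=int)
        block[study & (days < 6.5)] = 1
        block[study & (days >= 6.5) & (days < 12.5)] = 2
        block[study & (days >= 12.5)] = 3
        night = np.where((zt >= 12.0) & study, np.floor(days + 0.5), 0).astype(int)

        for name, prof in profiles.items():
            # mean per-interval level, evaluated blockwise (effects differ per block/night)
            lev = np.empty(days.size)
            for b in np.unique(block):
                m = block == b
                if name == "activity" and group == "pregnant" and b > 0:
                    for k in np.unique(night[m]):
                        mm = m & (night == k)
                        lev[mm] = mean_curve(prof, zt_mid[mm], group, int(b), effects, night=int(k))
                else:
                    lev[m] = mean_curve(prof, zt_mid[m], group, int(b), effects)
            alpha = rng.normal(0.0, prof.intercept_sd) if prof.intercept_sd > 0 else 0.0
            if name == "wake":
                mu = _expit(_logit(np.clip(lev, 1e-3, 1 - 1e-3)) + alpha)
                phi = prof.beta_precision
                value = rng.beta(mu * phi, (1.0 - mu) * phi)
            else:
                s = np.sqrt(lev / per_hour) + alpha
                if prof.noise_sd_sqrt > 0:
                    # behavioural noise is bout-like: one sqrt-scale deviation
                    # per mouse-hour, shared by that hour's intervals
                    hour_key = np.floor(days * 24.0 + 1e-9).astype(np.int64)
                    _, hour_pos = np.unique(hour_key, return_inverse=True)
                    eps = rng.normal(0.0, prof.noise_sd_sqrt, size=hour_pos.max() + 1)
                    s = s + eps[hour_pos]
                value = np.clip(s, 0.0, None) ** 2
            frames.append(
                pd.DataFrame(
                    {
                        "mouse_id": mouse_id,
                        "group": group,
                        "day": np.round(days, 8),
                        "zt_hour": np.round(zt, 8),
                        "behaviour": name,
                        "value": value,
                    }
                )
            )
    out = pd.concat(frames, ignore_index=True)
    return out


def inject_truth_log(
    config: CohortConfig,
    profiles: Optional[Dict[str, BehaviourProfileSpec]] = None,
    effects: Optional[PregnancyEffectSpec] = None,
) -> pd.DataFrame:
    """Ground-truth peak table for the configured cohort.

    One row per behaviour x block x window x group with the noise-free local
    maximum of the mean curve inside the window (time on the unwrapped ZT
    axis, amplitude in behaviour units), plus the pregnant-minus-nonpregnant
    differences.  Windows whose curve has no interior local maximum report
    NaN.  Also includes rows ``behaviour='onset'`` with the true per-night
    activity-onset delay.
    """
    profiles = profiles if profiles is not None else default_profiles()
    effects = effects if effects is not None else default_effects()
    step = 0.005
    t = np.round(np.arange(6.0, 30.0 + step / 2, step), 9)
    rows = []
    for name, prof in profiles.items():
        for block in (1, 2, 3):
            curves = {}
            for group in ("nonpregnant", "pregnant"):
                curves[group] = mean_curve(prof, t % 24.0, group, block, effects)
            for win, (lo, hi) in WINDOWS.items():
                rec = {"behaviour": name, "block": block, "window": win}
                for group in ("nonpregnant", "pregnant"):
                    v = curves[group]
                    interior = (
                        (v[1:-1] > v[:-2]) & (v[1:-1] > v[2:])
                        & (t[1:-1] >= lo) & (t[1:-1] < hi)
                    )
                    idx = np.flatnonzero(interior) + 1
                    if idx.size:
                        best = idx[np.argmax(v[idx])]
                        rec[f"time_{group}"] = float(t[best])
                        rec[f"amp_{group}"] = float(v[best])
                    else:
                        rec[f"time_{group}"] = np.nan
                        rec[f"amp_{group}"] = np.nan
                rec["time_diff"] = rec["time_pregnant"] - rec["time_nonpregnant"]
                rec["amp_diff"] = rec["amp_pregnant"] - rec["amp_nonpregnant"]
                rows.append(rec)
    truth = pd.DataFrame(rows)
    onset = pd.DataFrame(
        {
            "behaviour": "onset",
            "block": [1 if n <= 6 else 2 if n <= 12 else 3 for n in range(1, config.study_days + 1)],
            "window": [f"night{n}" for n in range(1, config.study_days + 1)],
            "time_diff": [effects.night_delay(n) for n in range(1, config.study_days + 1)],
        }
    )
    return pd.concat([truth, onset], ignore_index=True)


def write_cohort(records: pd.DataFrame, path) -> None:
    records[RAW_COLUMNS].to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(RAW_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"raw record CSV missing columns: {sorted(missing)}")
    return df


def write_config(config: CohortConfig, path) -> None:
    d = dataclasses.asdict(config)
    d["termination_schedule"] = {k: list(v) for k, v in d["termination_schedule"].items()}
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh)


def read_config(path) -> CohortConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    d["termination_schedule"] = {k: tuple(v) for k, v in d["termination_schedule"].items()}
    return CohortConfig(**d)
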