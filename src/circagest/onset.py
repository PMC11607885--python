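"""Dark-phase activity-onset detection and group comparison.

Each mouse's activity threshold is the arithmetic mean of its 5-min
dark-phase activity over the acclimation period.  Onset on a given night is
the start time (hours after lights-off, 5-min resolution) of the first run
of three consecutive 5-min blocks whose activity strictly exceeds the
threshold; nights without such a run are censored at 12 h and enter the
group model at that value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

BLOCK_H = 300 / 3600.0
CENSOR_H = 12.0
RUN_LEN = 3


def acclimation_threshold(blocks: pd.DataFrame) -> pd.DataFrame:
    """Per-mouse activity threshold (m per 5 min): mean of all acclimation
    dark-phase 5-min activity blocks.  Raises if a mouse has none."""
    acc = blocks[
        (blocks["behaviour"] == "activity")
        & (blocks["day"] < 0)
        & (blocks["zt_start"] >= 12.0)
        & (blocks["zt_start"] < 24.0)
    ]
    if acc.empty:
        raise ValueError("no acclimation dark-phase activity blocks")
    thr = acc.groupby("mouse_id")["value"].mean().rename("threshold").reset_index()
    return thr


def detect_onset(zt_start: np.ndarray, values: np.ndarray, threshold: float) -> tuple[float, bool]:
    """Onset for one night from its dark-phase 5-min blocks.

    ``zt_start`` are block start times in ZT hours (within [12, 24)),
    ``values`` the matching activity per 5 min.  Gaps in the block sequence
    break runs (a missing block never counts as above threshold).  Returns
    (onset hours after lights-off, censored flag); onset == 12.0 iff censored.
    """
    zt_start = np.asarray(zt_start, dtype=float)
    values = np.asarray(values, dtype=float)
    order = np.argsort(zt_start)
    zt_start, values = zt_start[order], values[order]
    idx = np.round((zt_start - 12.0) / BLOCK_H).astype(int)
    above = values > threshold
    run = 0
    for k in range(idx.size):
        if above[k] and k > 0 and idx[k] == idx[k - 1] + 1 and run > 0:
            run += 1
        elif above[k]:
            run = 1
        else:
            run = 0
        if run >= RUN_LEN:
            start = idx[k] - (RUN_LEN - 1)
            return start * BLOCK_H, False
    return CENSOR_H, True


def onsets_by_night(blocks: pd.DataFrame, thresholds: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Per-mouse, per-night onset table over all nights present in the
    5-min block table (acclimation nights get labels <= 0)."""
    if thresholds is None:
        thresholds = acclimation_threshold(blocks)
    thr = dict(zip(thresholds["mouse_id"], thresholds["threshold"]))
    act = blocks[
        (blocks["behaviour"] == "activity")
        & (blocks["zt_start"] >= 12.0)
        & (blocks["zt_start"] < 24.0)
    ].copy()
    # night k spans decimal days [k - 0.5, k)
    act["night"] = np.floor(np.round(act["day"], 9) + 0.5).astype(int)
    rows = []
    for (mouse, night), g in act.groupby(["mouse_id", "night"], sort=True):
        if mouse not in thr:
            continue
        onset, censored = detect_onset(g["zt_start"].values, g["value"].values, thr[mouse])
        rows.append(
            {
                "mouse_id": mouse,
                "group": g["group"].iloc[0],
                "night": night,
                "phase": "acclimation" if night <= 0 else "study",
                "onset": onset,
                "censored": censored,
            }
        )
    return pd.DataFrame(rows)


def validate_acclimation(onsets: pd.DataFrame, within_h: float = 2.0) -> dict:
    """Share of acclimation mouse-nights with onset within ``within_h`` of
    lights-off, and share of mice achieving that on at least one night."""
    acc = onsets[onsets["phase"] == "acclimation"] if "phase" in onsets else onsets
    if acc.empty:
        return {"fraction_nights": np.nan, "fraction_mice": np.nan}
    ok = acc["onset"] <= within_h
    per_mouse = ok.groupby(acc["mouse_id"]).any()
    return {
        "fraction_nights": float(ok.mean()),
        "fraction_mice": float(per_mouse.mean()),
    }


@dataclass
class OnsetModelResult:
    """Mixed-model comparison of onset times: pregnancy x study night fixed
    effects with a random intercept per mouse."""

    per_day: pd.DataFrame          # night, difference (pregnant - nonpregnant), se, p
    interaction_stat: float        # Wald chi-square for the interaction
    interaction_df: int
    interaction_p: float
    converged: bool
    model: object = None


def onset_group_model(onsets: pd.DataFrame) -> OnsetModelResult:
    """Fit the linear mixed model ``onset ~ C(night) * group`` with a random
    intercept per mouse; report per-night group differences (two-sided Wald
    contrasts, unadjusted) and the interaction test.

    On balanced complete data the per-night differences equal the raw
    pregnant-minus-nonpregnant cell-mean differences.
    """
    df = onsets[onsets["phase"] == "study"].copy() if "phase" in onsets else onsets.copy()
    df["preg"] = (df["group"] == "pregnant").astype(float)
    nights = sorted(df["night"].unique())
    for g in ("pregnant", "nonpregnant"):
        if df.loc[df["group"] == g, "mouse_id"].nunique() < 2:
            raise ValueError(f"need >= 2 mice in group {g}")
    converged = True
    fit = None
    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md = smf.mixedlm("onset ~ C(night) * preg", data=df, groups=df["mouse_id"])
            try:
                fit = md.fit(reml=True, method="lbfgs", maxiter=200)
            except np.linalg.LinAlgError:
                fit = md.fit(reml=True, method="powell", maxiter=500)
            converged = bool(fit.converged)
            names = list(fit.fe_params.index)
            params = fit.fe_params.values
            cov = fit.cov_params().loc[names, names].values
            if not np.all(np.isfinite(cov)):
                raise np.linalg.LinAlgError("non-finite covariance")
    except (np.linalg.LinAlgError, ValueError):
        # singular mixed fit (e.g. zero residual variance): report it and fall
        # back to the fixed-effect model, whose estimates coincide on balanced
        # data
        converged = False
        ols = smf.ols("onset ~ C(night) * preg", data=df).fit()
        names = list(ols.params.index)
        params = ols.params.values
        cov = ols.cov_params().values
        fit = ols

    base = nights[0]
    rows = []
    for night in nights:
        L = np.zeros(len(names))
        L[names.index("preg")] = 1.0
        if night != base:
            key = f"C(night)[T.{night}]:preg"
            if key in names:
                L[names.index(key)] = 1.0
        est = float(L @ params)
        se = float(np.sqrt(L @ cov @ L))
        from scipy.stats import norm

        p = 2 * norm.sf(abs(est) / se) if se > 0 else np.nan
        rows.append({"night": night, "difference": est, "se": se, "p": p})
    per_day = pd.DataFrame(rows)

    inter_idx = [i for i, n in enumerate(names) if ":preg" in n]
    if inter_idx:
        b = params[inter_idx]
        V = cov[np.ix_(inter_idx, inter_idx)]
        from scipy.stats import chi2

        if np.max(np.abs(b)) < 1e-8:  # numerically null interaction
            stat = 0.0
        else:
            stat = float(b @ np.linalg.pinv(V) @ b)
        dfree = len(inter_idx)
        p_int = float(chi2.sf(stat, dfree))
    else:
        stat, dfree, p_int = np.nan, 0, np.nan
    return OnsetModelResult(
        per_day=per_day,
        interaction_stat=stat,
        interaction_df=dfree,
        interaction_p=p_int,
        converged=converged,
        model=fit,
    )
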