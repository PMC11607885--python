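"""Bayesian natural-spline multilevel models of the circadian behaviours.

Two-stage analysis:

1. :func:`fit_acclimation` models the 7-day acclimation period (spline x
   group fixed effects, random intercept per mouse) and extracts a per-mouse
   baseline profile on the model's link scale (sqrt for food/water/activity,
   logit for wakefulness) at each ZT hour.
2. :func:`fit_behaviour_model` models the study period: natural spline
   (13 knots, ZT8.5-ZT28.5) in a full three-way interaction with pregnancy
   group and study block (cell-means parametrisation: one intercept + spline
   per group-block cell), plus the mouse's centred acclimation profile as a
   linear covariate, with nested random intercepts (mouse, and block within
   mouse).  Food, water and activity are fitted on the square-root scale
   with Gaussian errors; wakefulness with a beta likelihood on the logit
   scale.  Posterior group-by-block mean curves are returned on the response
   scale on a 0.05 h grid over ZT6-ZT30.

Hourly observations are placed at the centre of their hour (ZT h + 0.5).
Sqrt-scale curves are back-transformed per draw as (sqrt-mean)^2 + residual
variance, the mean of a squared Gaussian.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .samplers import (
    REDUCED,
    PosteriorDraws,
    SamplerSettings,
    gibbs_gaussian,
    mwg_beta,
)
from .splines import SplineBasis, unwrap_zt, zt_grid

logger = logging.getLogger(__name__)

GAUSSIAN_BEHAVIOURS = ("food", "water", "activity")
#: wake fractions exactly 0/1 are nudged by half a second out of 300
WAKE_EPS = 1.0 / 600.0

RHAT_LIMIT = 1.05


def family_for(behaviour: str) -> str:
    return "beta_logit" if behaviour == "wake" else "gaussian_sqrt"


def back_transform_sqrt(mean_sqrt, var_sqrt):
    """Response-scale mean of X when sqrt(X) ~ Normal(mean_sqrt, var_sqrt):
    E[X] = mean_sqrt**2 + var_sqrt."""
    var_sqrt = np.asarray(var_sqrt, dtype=float)
    if np.any(var_sqrt < 0):
        raise ValueError("variance must be non-negative")
    return np.asarray(mean_sqrt, dtype=float) ** 2 + var_sqrt


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p):
    return np.log(p / (1.0 - p))


def _link_transform(values: np.ndarray, behaviour: str) -> np.ndarray:
    if behaviour == "wake":
        return _logit(np.clip(values, WAKE_EPS, 1.0 - WAKE_EPS))
    if np.any(values < 0):
        raise ValueError("sqrt family needs non-negative responses")
    return np.sqrt(values)


@dataclass
class ModelSpec:
    """Model configuration for one behaviour."""

    behaviour: str
    settings: SamplerSettings = field(default_factory=lambda: REDUCED)
    seed: int = 0
    knots: Optional[np.ndarray] = None

    @property
    def family(self) -> str:
        return family_for(self.behaviour)


@dataclass
class AcclimationProfiles:
    """Per-mouse link-scale baseline estimates at each ZT hour.

    Also carries the stage-1 group-level spline coefficients so that the
    stage-2 model can reconstruct the covariate's group-mean time profile on
    an arbitrary grid (needed to put the shared circadian shape back into
    predicted group curves; the covariate is centred in the design).
    """

    behaviour: str
    table: pd.DataFrame  # mouse_id, zt_hour, estimate
    group_means: pd.DataFrame  # group, zt_hour, estimate (fallback profile)
    knots: Optional[np.ndarray] = None
    group_coefs: Optional[Dict[str, np.ndarray]] = None
    group_coef_draws: Optional[Dict[str, np.ndarray]] = None  # (n_draws, q)

    def group_curve(self, group: str, t) -> np.ndarray:
        """Link-scale stage-1 group curve at unwrapped times ``t``."""
        from .splines import SplineBasis

        basis = SplineBasis() if self.knots is None else SplineBasis(self.knots)
        return basis.design(np.asarray(t, float)) @ self.group_coefs[group]

    def group_curve_draws(self, group: str, t, n: int) -> np.ndarray:
        """``n`` draws of the stage-1 group curve at times ``t`` (cycled),
        so stage-1 estimation uncertainty propagates into stage-2 curves."""
        from .splines import SplineBasis

        basis = SplineBasis() if self.knots is None else SplineBasis(self.knots)
        B = basis.design(np.asarray(t, float))
        draws = self.group_coef_draws[group]
        idx = np.arange(n) % draws.shape[0]
        return draws[idx] @ B.T

    def lookup(self, mouse_ids, groups, zt_hours) -> np.ndarray:
        key = self.table.set_index(["mouse_id", "zt_hour"])["estimate"]
        fallback = self.group_means.set_index(["group", "zt_hour"])["estimate"]
        out = np.empty(len(mouse_ids))
        warned = set()
        for i, (m, g, h) in enumerate(zip(mouse_ids, groups, zt_hours)):
            try:
                out[i] = key.loc[(m, int(h))]
            except KeyError:
                if m not in warned:
                    logger.warning("mouse %s missing from acclimation; using group profile", m)
                    warned.add(m)
                out[i] = fallback.loc[(g, int(h))]
        return out


@dataclass
class PosteriorCurves:
    """Posterior fitted mean curves for every group x study block."""

    behaviour: str
    zt_grid: np.ndarray                           # (G,) unwrapped ZT6-ZT30
    draws: Dict[Tuple[str, int], np.ndarray]      # (group, block) -> (n_draws, G) response scale
    link_draws: Dict[Tuple[str, int], np.ndarray]
    sigma2: np.ndarray                            # per-draw residual variance (gaussian; NaN for beta)
    rhat_max: float
    converged: bool

    def save(self, path) -> None:
        """Persist draws to NPZ: arrays ``resp_<group>_<block>`` and
        ``link_<group>_<block>`` of shape (draw, grid), plus grid/sigma2."""
        arrays = {"zt_grid": self.zt_grid, "sigma2": self.sigma2,
                  "rhat_max": np.array(self.rhat_max)}
        for (g, b), d in self.draws.items():
            arrays[f"resp_{g}_{b}"] = d
            arrays[f"link_{g}_{b}"] = self.link_draws[(g, b)]
        np.savez_compressed(path, behaviour=np.array(self.behaviour), **arrays)

    @classmethod
    def load(cls, path) -> "PosteriorCurves":
        z = np.load(path, allow_pickle=False)
        draws, link = {}, {}
        for key in z.files:
            if key.startswith("resp_"):
                _, g, b = key.split("_")
                draws[(g, int(b))] = z[key]
                link[(g, int(b))] = z[f"link_{g}_{b}"]
        rhat = float(z["rhat_max"])
        return cls(
            behaviour=str(z["behaviour"]), zt_grid=z["zt_grid"], draws=draws,
            link_draws=link, sigma2=z["sigma2"], rhat_max=rhat,
            converged=bool(np.isnan(rhat) or rhat <= RHAT_LIMIT),
        )

    def summary(self) -> pd.DataFrame:
        rows = []
        for (group, block), d in self.draws.items():
            rows.append(
                pd.DataFrame(
                    {
                        "behaviour": self.behaviour,
                        "group": group,
                        "study_block": block,
                        "zt": self.zt_grid,
                        "mean": d.mean(axis=0),
                        "lo2.5": np.quantile(d, 0.025, axis=0),
                        "hi97.5": np.quantile(d, 0.975, axis=0),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def _prepare(df: pd.DataFrame, behaviour: str) -> pd.DataFrame:
    sub = df[(df["behaviour"] == behaviour)].dropna(subset=["value"]).copy()
    sub["t"] = unwrap_zt(sub["zt_hour"].to_numpy(float) + 0.5)
    return sub


def fit_acclimation(
    hourly: pd.DataFrame,
    behaviour: str,
    settings: SamplerSettings = REDUCED,
    seed: int = 0,
    knots: Optional[np.ndarray] = None,
) -> AcclimationProfiles:
    """Stage-1 model of the acclimation period.

    Fits spline x group fixed effects with a random intercept per mouse and
    returns each mouse's posterior-mean profile (group curve + the mouse's
    intercept) on the link scale at every ZT hour.
    """
    acc = _prepare(hourly[hourly["phase"] == "acclimation"], behaviour)
    if acc.empty:
        raise ValueError("no acclimation data")
    basis = SplineBasis() if knots is None else SplineBasis(np.asarray(knots))
    y = _link_transform(acc["value"].to_numpy(float), behaviour)
    groups = sorted(acc["group"].unique())
    B = basis.design(acc["t"].to_numpy())
    q = B.shape[1]
    X = np.zeros((len(acc), q * len(groups)))
    for j, g in enumerate(groups):
        m = (acc["group"] == g).to_numpy()
        X[m, j * q : (j + 1) * q] = B[m]
    mice = sorted(acc["mouse_id"].unique())
    mouse_idx = acc["mouse_id"].map({m: i for i, m in enumerate(mice)}).to_numpy()
    cell_idx = mouse_idx  # single period: the nested level coincides with mouse

    if behaviour == "wake":
        blocks = [
            (np.arange(j * q, (j + 1) * q), np.flatnonzero((acc["group"] == g).to_numpy()))
            for j, g in enumerate(groups)
        ]
        yb = acc["value"].clip(WAKE_EPS, 1 - WAKE_EPS).to_numpy()
        post = mwg_beta(yb, X, mouse_idx, cell_idx, blocks, settings, seed)
    else:
        post = gibbs_gaussian(y, X, mouse_idx, cell_idx, settings, seed)

    beta_mean = post.beta.mean(axis=0)
    # posterior-mean mouse offset: refit by residual means is avoided; draw-free
    # BLUP-style estimate from the posterior means of the variance components
    fitted = X @ beta_mean
    resid = y - fitted
    s2m = float(np.mean(post.sigma2_mouse) + np.mean(post.sigma2_cell))
    s2 = float(np.nanmean(post.sigma2)) if np.isfinite(post.sigma2).any() else float(np.var(resid))
    n_m = np.bincount(mouse_idx)
    shrink = s2m / (s2m + s2 / np.maximum(n_m, 1))
    u = shrink * np.bincount(mouse_idx, weights=resid) / np.maximum(n_m, 1)

    hours = np.arange(24)
    t_hours = unwrap_zt(hours + 0.5)
    Bh = basis.design(t_hours)
    rows = []
    gm = []
    coefs = {}
    coef_draws = {}
    mouse_group = acc.drop_duplicates("mouse_id").set_index("mouse_id")["group"]
    for j, g in enumerate(groups):
        coefs[g] = beta_mean[j * q : (j + 1) * q]
        coef_draws[g] = post.beta[:, j * q : (j + 1) * q]
        curve = Bh @ coefs[g]
        gm.append(pd.DataFrame({"group": g, "zt_hour": hours, "estimate": curve}))
        for i, m in enumerate(mice):
            if mouse_group.loc[m] != g:
                continue
            rows.append(pd.DataFrame({"mouse_id": m, "zt_hour": hours, "estimate": curve + u[i]}))
    return AcclimationProfiles(
        behaviour,
        pd.concat(rows, ignore_index=True),
        pd.concat(gm, ignore_index=True),
        knots=basis.knots,
        group_coefs=coefs,
        group_coef_draws=coef_draws,
    )


def build_design(
    study: pd.DataFrame, basis: SplineBasis, acc_cov: np.ndarray
) -> Tuple[np.ndarray, List[Tuple[str, int]], List[Tuple[np.ndarray, np.ndarray]], np.ndarray, np.ndarray]:
    """Cell-means design: per group x block cell an intercept + spline block,
    plus one centred acclimation-covariate column (the last column).

    Returns (X, cells, param_blocks, mouse_idx, cell_idx).
    """
    B = basis.design(study["t"].to_numpy())
    q = B.shape[1]
    cells = sorted(
        {(g, int(b)) for g, b in zip(study["group"], study["study_block"])},
        key=lambda c: (c[0], c[1]),
    )
    X = np.zeros((len(study), q * len(cells) + 1))
    param_blocks = []
    for j, (g, b) in enumerate(cells):
        m = ((study["group"] == g) & (study["study_block"] == b)).to_numpy()
        X[m, j * q : (j + 1) * q] = B[m]
        param_blocks.append((np.arange(j * q, (j + 1) * q), np.flatnonzero(m)))
    X[:, -1] = acc_cov - acc_cov.mean()
    param_blocks.append((np.array([q * len(cells)]), np.arange(len(study))))

    mice = sorted(study["mouse_id"].unique())
    mouse_idx = study["mouse_id"].map({m: i for i, m in enumerate(mice)}).to_numpy()
    mb = sorted(set(zip(study["mouse_id"], study["study_block"])))
    cell_idx = (
        pd.Series(list(zip(study["mouse_id"], study["study_block"])))
        .map({c: i for i, c in enumerate(mb)})
        .to_numpy()
    )
    return X, cells, param_blocks, mouse_idx, cell_idx


def fit_behaviour_model(
    hourly: pd.DataFrame,
    profiles: Optional[AcclimationProfiles],
    spec: ModelSpec,
) -> PosteriorCurves:
    """Fit the study-period model for one behaviour and return posterior
    group x block mean curves on the response scale.

    Cells with fewer than 2 mice raise; a maximum split-R-hat above 1.05
    flags the result as non-converged (peak analysis refuses flagged fits
    unless forced).
    """
    study = _prepare(hourly[(hourly["phase"] == "study") & (hourly["study_block"] > 0)], spec.behaviour)
    if study.empty:
        raise ValueError("no study data")
    counts = study.groupby(["group", "study_block"])["mouse_id"].nunique()
    if (counts < 2).any():
        raise ValueError(f"need >= 2 mice per group-block cell, got:\n{counts}")
    basis = SplineBasis() if spec.knots is None else SplineBasis(np.asarray(spec.knots))
    if profiles is not None:
        acc_cov = profiles.lookup(
            study["mouse_id"].to_numpy(), study["group"].to_numpy(), study["zt_hour"].to_numpy()
        )
    else:
        acc_cov = np.zeros(len(study))
    X, cells, param_blocks, mouse_idx, cell_idx = build_design(study, basis, acc_cov)
    if profiles is None:
        X = X[:, :-1]
        param_blocks = param_blocks[:-1]

    values = study["value"].to_numpy(float)
    if spec.behaviour == "wake":
        y = np.clip(values, WAKE_EPS, 1.0 - WAKE_EPS)
        cov_move = None
        if profiles is not None:
            # likelihood-invariant direction: the covariate is (group stage-1
            # curve + mouse offset - centring), all of which the cell splines
            # and mouse intercepts can absorb
            q = (X.shape[1] - 1) // len(cells)
            c0 = float(acc_cov.mean())
            s_beta = np.zeros(X.shape[1])
            s_beta[-1] = 1.0
            for j, (g, b) in enumerate(cells):
                s_beta[j * q : (j + 1) * q] = -profiles.group_coefs[g]
                s_beta[j * q] += c0
            mice = sorted(study["mouse_id"].unique())
            mouse_groups = study.drop_duplicates("mouse_id").set_index("mouse_id")["group"]
            prof0 = profiles.table[profiles.table["zt_hour"] == 0].set_index("mouse_id")["estimate"]
            gm0 = profiles.group_means[profiles.group_means["zt_hour"] == 0].set_index("group")["estimate"]
            s_u = np.zeros(len(mice))
            for i, m in enumerate(mice):
                if m in prof0.index:
                    s_u[i] = -(prof0.loc[m] - gm0.loc[mouse_groups.loc[m]])
            cov_move = (s_beta, s_u)
        post = mwg_beta(y, X, mouse_idx, cell_idx, param_blocks, spec.settings, spec.seed,
                        cov_move=cov_move)
    else:
        y = _link_transform(values, spec.behaviour)
        post = gibbs_gaussian(y, X, mouse_idx, cell_idx, spec.settings, spec.seed)

    grid = zt_grid()
    Bg = basis.design(grid)
    q = Bg.shape[1]
    draws, link_draws = {}, {}
    # the covariate is centred, so predicted group curves must restore the
    # shared circadian shape it carries: + gamma * (group stage-1 curve - c0)
    if profiles is not None:
        c0 = float(acc_cov.mean())
        gamma = post.beta[:, -1]
        n_draws = post.beta.shape[0]
        acc_term = {
            g: gamma[:, None] * (profiles.group_curve_draws(g, grid, n_draws) - c0)
            for g in {c[0] for c in cells}
        }
    for j, cell in enumerate(cells):
        link = post.beta[:, j * q : (j + 1) * q] @ Bg.T  # (n_draws, G)
        if profiles is not None:
            link = link + acc_term[cell[0]]
        link_draws[cell] = link
        if spec.behaviour == "wake":
            draws[cell] = _expit(link)
        else:
            draws[cell] = back_transform_sqrt(link, post.sigma2[:, None])
    rhat = post.rhat_max
    converged = bool(np.isnan(rhat) or rhat <= RHAT_LIMIT)
    if not converged:
        logger.warning("%s model flagged: max split-R-hat %.3f", spec.behaviour, rhat)
    return PosteriorCurves(
        behaviour=spec.behaviour,
        zt_grid=grid,
        draws=draws,
        link_draws=link_draws,
        sigma2=post.sigma2,
        rhat_max=rhat,
        converged=converged,
    )


def curves_to_report(curves: PosteriorCurves) -> pd.DataFrame:
    """Plot-ready table: grid, posterior mean and 2.5/97.5% quantiles per
    group x block on the response scale."""
    if not curves.draws or any(d.shape[0] == 0 for d in curves.draws.values()):
        raise ValueError("empty posterior draw set")
    return curves.summary()
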