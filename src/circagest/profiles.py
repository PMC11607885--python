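"""Ground-truth behaviour profiles and pregnancy effects for the synthetic cohort.

A behaviour's daily mean curve is a smooth periodic baseline (periodic cubic
interpolant through control points on [0, 24)) plus a set of localised
Gaussian bumps, one per circadian window of interest.  Pregnancy effects act
on the bumps (per study block: time delays and amplitude fold-changes per
window), on the dark-phase level as a whole (activity scaling), and on the
time of dark-phase activity onset (a per-night activity gate).

The five windows of local behaviour, on the unwrapped ZT6-ZT30 axis:

    I   [ZT8,  ZT12)   late light phase
    II  [ZT12, ZT15)   early dark phase
    III [ZT15, ZT18)   mid dark phase
    IV  [ZT18, ZT24)   late dark phase
    V   [ZT24, ZT28)   early light phase of the next cycle (ZT0-ZT4)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.interpolate import PchipInterpolator

from .splines import unwrap_zt

BEHAVIOURS = ("food", "water", "activity", "wake")

#: window id -> [start, end) on the unwrapped ZT axis
WINDOWS: Dict[str, Tuple[float, float]] = {
    "I": (8.0, 12.0),
    "II": (12.0, 15.0),
    "III": (15.0, 18.0),
    "IV": (18.0, 24.0),
    "V": (24.0, 28.0),
}
WINDOW_IDS = tuple(WINDOWS)

DARK = (12.0, 24.0)  # lights off at ZT12 under the 12:12 cycle


def circ_diff(a, b):
    """Signed circular difference a - b wrapped to (-12, 12] hours."""
    d = (np.asarray(a, dtype=float) - b) % 24.0
    return np.where(d > 12.0, d - 24.0, d)


@dataclass
class PeakSpec:
    """One localised bump of behaviour: window membership, centre (ZT h),
    height above the baseline (behaviour units) and Gaussian width (h)."""

    window: str
    time: float
    amplitude: float
    width: float = 1.3

    def __post_init__(self):
        lo, hi = WINDOWS[self.window]
        t = unwrap_zt(np.array(self.time)).item()
        if not (lo <= t < hi):
            raise ValueError(f"peak time ZT{self.time} outside window {self.window} [{lo},{hi})")
        if self.amplitude < 0:
            raise ValueError("peak amplitude must be >= 0")


@dataclass
class BehaviourProfileSpec:
    """Ground-truth mean curve of one behaviour plus its noise model.

    ``baseline_points`` are (zt, level) control points interpolated with a
    periodic cubic spline over [0, 24); intake/activity levels are per-hour
    units (g/h, m/h), wake levels are fractions in (0, 1).  Intake/activity
    records are generated on the square-root scale with per-interval Gaussian
    noise ``noise_sd_sqrt`` and a per-mouse intercept with SD
    ``intercept_sd``; wake fractions are Beta draws with precision
    ``beta_precision`` around the (logit-shifted) profile mean.
    """

    behaviour: str
    baseline_points: Sequence[Tuple[float, float]]
    peaks: List[PeakSpec] = field(default_factory=list)
    noise_sd_sqrt: float = 0.0
    beta_precision: float = 50.0
    intercept_sd: float = 0.0

    def __post_init__(self):
        if self.behaviour not in BEHAVIOURS:
            raise ValueError(f"unknown behaviour {self.behaviour!r}")
        pts = sorted((float(z) % 24.0, float(v)) for z, v in self.baseline_points)
        if any(v < 0 for _, v in pts):
            raise ValueError("baseline levels must be >= 0")
        if self.behaviour == "wake" and any(not (0 < v < 1) for _, v in pts):
            raise ValueError("wake levels must lie in (0, 1)")
        if self.beta_precision <= 0:
            raise ValueError("beta_precision must be > 0")
        self._pts = pts
        zs = np.array([z for z, _ in pts])
        vs = np.array([v for _, v in pts])
        # shape-preserving periodic interpolant: wrap the control points one
        # cycle either side and use PCHIP (no over/undershoot at sharp turns)
        zext = np.concatenate([zs - 24.0, zs, zs + 24.0])
        vext = np.concatenate([vs, vs, vs])
        self._interp = PchipInterpolator(zext, vext)

    def baseline(self, zt) -> np.ndarray:
        """Smooth periodic baseline level at ZT hours (array-safe)."""
        return self._interp(np.asarray(zt, dtype=float) % 24.0)

    def curve(
        self,
        zt,
        delays: Optional[Dict[str, float]] = None,
        folds: Optional[Dict[str, float]] = None,
    ) -> np.ndarray:
        """Mean curve at ZT hours, with optional per-window peak-time delays
        (h) and amplitude fold-changes applied to the bumps.

        Wake curves are clipped into (0.001, 0.999); others to >= 0.
        """
        zt = np.asarray(zt, dtype=float)
        out = self.baseline(zt).astype(float)
        for pk in self.peaks:
            t = pk.time + (delays or {}).get(pk.window, 0.0)
            a = pk.amplitude * (folds or {}).get(pk.window, 1.0)
            out = out + a * np.exp(-0.5 * (circ_diff(zt, t) / pk.width) ** 2)
        if self.behaviour == "wake":
            return np.clip(out, 1e-3, 1.0 - 1e-3)
        return np.clip(out, 0.0, None)

    def dark_fraction(self) -> float:
        """Fraction of the daily integral falling in the dark phase
        (ZT12-ZT24) for the unmodified profile (noise-free)."""
        zt = np.arange(0.0, 24.0, 0.01)
        v = self.curve(zt)
        dark = (zt >= DARK[0]) & (zt < DARK[1])
        return float(v[dark].sum() / v.sum())


@dataclass
class PregnancyEffectSpec:
    """Effects of pregnancy on the mean curves, per study block (1, 2, 3).

    ``amplitude_fold[block][(behaviour, window)]`` multiplies the bump height;
    ``peak_delay[block][(behaviour, window)]`` shifts the bump centre (h,
    positive = later); ``activity_scale_dark[block]`` in (0, 1] multiplies the
    dark-phase activity curve; ``onset_delay[night]`` (h, one entry per study
    night, monotone non-decreasing by convention of a progressing pregnancy)
    suppresses pregnant activity for that long after lights-off.
    """

    amplitude_fold: Dict[int, Dict[Tuple[str, str], float]] = field(default_factory=dict)
    peak_delay: Dict[int, Dict[Tuple[str, str], float]] = field(default_factory=dict)
    activity_scale_dark: Dict[int, float] = field(default_factory=dict)
    onset_delay: np.ndarray = field(default_factory=lambda: np.zeros(17))

    def __post_init__(self):
        self.onset_delay = np.asarray(self.onset_delay, dtype=float)
        if np.any(self.onset_delay < 0):
            raise ValueError("onset_delay must be >= 0")
        for blk, s in self.activity_scale_dark.items():
            if not (0 < s <= 1):
                raise ValueError(f"activity_scale_dark[{blk}] must lie in (0, 1]")
        for d in self.peak_delay.values():
            if any(not np.isfinite(v) for v in d.values()):
                raise ValueError("peak delays must be finite")

    def folds_for(self, behaviour: str, block: int) -> Dict[str, float]:
        return {
            w: f
            for (b, w), f in self.amplitude_fold.get(block, {}).items()
            if b == behaviour
        }

    def delays_for(self, behaviour: str, block: int) -> Dict[str, float]:
        return {
            w: d
            for (b, w), d in self.peak_delay.get(block, {}).items()
            if b == behaviour
        }

    def night_delay(self, night: int) -> float:
        """Activity-onset suppression (h) for study night 1..N."""
        if night < 1 or night > len(self.onset_delay):
            return 0.0
        return float(self.onset_delay[night - 1])


@dataclass
class CohortConfig:
    """Virtual-cohort layout mirroring the study design: individually housed
    mice under 12:12 LD, 7 acclimation days, then up to 17 study days with
    staged terminations at days 6.5, 12.5 and 17.5."""

    n_nonpregnant: int = 12
    n_pregnant: int = 31
    termination_schedule: Dict[str, Tuple[int, int, int]] = field(
        default_factory=lambda: {"nonpregnant": (4, 2, 6), "pregnant": (10, 10, 11)}
    )
    acclimation_days: int = 7
    study_days: int = 17
    sampling_interval: int = 300  # seconds
    random_seed: Optional[int] = None

    TERMINATION_DAYS = (6.5, 12.5, 17.5)

    def __post_init__(self):
        if self.n_nonpregnant <= 0 or self.n_pregnant <= 0:
            raise ValueError("group sizes must be positive")
        if 3600 % self.sampling_interval != 0:
            raise ValueError("sampling_interval must divide 3600")
        for grp, n in (("nonpregnant", self.n_nonpregnant), ("pregnant", self.n_pregnant)):
            sched = self.termination_schedule[grp]
            if len(sched) != 3 or sum(sched) != n:
                raise ValueError(f"termination counts for {grp} must sum to {n}")

    def termination_day(self, group: str, index_in_group: int) -> float:
        """Study day at which mouse ``index_in_group`` (0-based) is removed."""
        sched = self.termination_schedule[group]
        bounds = np.cumsum(sched)
        k = int(np.searchsorted(bounds, index_in_group, side="right"))
        return self.TERMINATION_DAYS[k]


# ---------------------------------------------------------------------------
# Default study conditions
# ---------------------------------------------------------------------------

def default_profiles() -> Dict[str, BehaviourProfileSpec]:
    """Nocturnally biased default profiles.

    Levels approximate the non-pregnant raw means of the study system: food
    ~0.02-0.09 g/h in the light phase rising to ~0.17-0.24 g/h bumps in the
    dark; activity a few m/h by day and tens of m/h at night; wakefulness
    ~20-35% by day and ~75-85% at night.  The dark phase carries ~70% of
    daily food intake.
    """
    food = BehaviourProfileSpec(
        "food",
        baseline_points=[(0, 0.050), (2, 0.050), (5, 0.055), (8, 0.060),
                         (11.3, 0.014), (12.7, 0.024), (14.0, 0.085), (15.9, 0.075),
                         (18, 0.095), (20.5, 0.100), (23, 0.075)],
        peaks=[
            PeakSpec("I", 8.8, 0.100, width=1.1),
            PeakSpec("II", 13.9, 0.210, width=1.0),
            PeakSpec("III", 17.3, 0.170, width=1.0),
            PeakSpec("IV", 22.0, 0.110, width=1.2),
            PeakSpec("V", 1.5, 0.070, width=1.2),
        ],
        noise_sd_sqrt=0.032,
        intercept_sd=0.006,
    )
    water = BehaviourProfileSpec(
        "water",
        baseline_points=[(0, 0.050), (2, 0.050), (5, 0.040), (8, 0.045),
                         (11.3, 0.020), (12.7, 0.026), (14.0, 0.090), (15.9, 0.080),
                         (18, 0.100), (20.5, 0.110), (23, 0.078)],
        # water peaks share the food peak times (drinking is meal-coupled)
        peaks=[
            PeakSpec("I", 9.0, 0.100, width=1.1),
            PeakSpec("II", 13.9, 0.190, width=1.0),
            PeakSpec("III", 17.3, 0.180, width=1.0),
            PeakSpec("IV", 22.0, 0.120, width=1.2),
            PeakSpec("V", 1.8, 0.085, width=1.2),
        ],
        noise_sd_sqrt=0.032,
        intercept_sd=0.006,
    )
    activity = BehaviourProfileSpec(
        "activity",
        baseline_points=[(0, 3.4), (2, 3.2), (5, 1.8), (8, 2.2), (11.5, 2.6),
                         (13.0, 10.0), (15.5, 10.0), (18, 9.5), (20.5, 10.0), (23, 5.0)],
        peaks=[
            PeakSpec("I", 8.8, 2.5, width=1.0),
            PeakSpec("II", 13.4, 15.0, width=1.0),
            PeakSpec("III", 17.2, 13.0, width=1.0),
            PeakSpec("IV", 22.0, 10.0, width=1.0),
            PeakSpec("V", 2.0, 6.0, width=1.2),
        ],
        noise_sd_sqrt=0.064,
        intercept_sd=0.06,
    )
    wake = BehaviourProfileSpec(
        "wake",
        baseline_points=[(0, 0.27), (2, 0.25), (5, 0.17), (8, 0.20), (11.5, 0.23),
                         (13.0, 0.52), (15.5, 0.52), (18, 0.51), (20.5, 0.52), (23, 0.33)],
        peaks=[
            PeakSpec("I", 8.8, 0.08, width=1.0),
            PeakSpec("II", 13.6, 0.27, width=1.0),
            PeakSpec("III", 17.3, 0.24, width=1.0),
            PeakSpec("IV", 22.2, 0.21, width=1.0),
            PeakSpec("V", 2.0, 0.15, width=1.2),
        ],
        beta_precision=40.0,
        intercept_sd=0.25,
    )
    return {"food": food, "water": water, "activity": activity, "wake": wake}


def default_effects() -> PregnancyEffectSpec:
    """Pregnancy effects emulating the study's findings: delayed and
    amplified late-light food/water peaks from mid-pregnancy, reduced and
    slightly delayed dark-phase activity/wakefulness, and a progressively
    delayed dark-phase activity onset (1.86 h on night 1 to 6.07 h on
    night 17)."""
    fold = {
        1: {("food", "II"): 1.35, ("activity", "I"): 0.6,
            ("wake", "II"): 0.89, ("wake", "III"): 0.62, ("wake", "IV"): 0.77},
        2: {("food", "I"): 2.0, ("food", "II"): 1.5,
            ("water", "I"): 1.5, ("water", "III"): 0.6,
            ("wake", "II"): 0.79, ("wake", "III"): 0.60, ("wake", "IV"): 0.79},
        3: {("food", "I"): 2.6, ("food", "II"): 1.8,
            ("water", "I"): 2.2, ("water", "II"): 2.3,
            ("wake", "II"): 0.75, ("wake", "III"): 0.58, ("wake", "IV"): 0.72},
    }
    delay = {
        1: {("activity", "IV"): 0.20, ("wake", "IV"): 0.11},
        2: {("food", "I"): 1.55, ("water", "I"): 1.30,
            ("activity", "IV"): 0.13, ("wake", "IV"): 0.11},
        3: {("food", "I"): 1.55, ("water", "IV"): 0.38},
    }
    scale = {1: 0.45, 2: 0.45, 3: 0.33}
    onset = np.linspace(1.86, 6.07, 17)
    return PregnancyEffectSpec(
        amplitude_fold=fold, peak_delay=delay,
        activity_scale_dark=scale, onset_delay=onset,
    )


def _smoothstep(x):
    """C1 ramp 0->1 on [0, 1]."""
    t = np.clip(x, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def mean_curve(
    profile: BehaviourProfileSpec,
    zt,
    group: str = "nonpregnant",
    block: int = 0,
    effects: Optional[PregnancyEffectSpec] = None,
    night: int = 0,
) -> np.ndarray:
    """Ground-truth mean level at ZT hours for one group x study block.

    For pregnant mice this applies the block's per-window delays and folds,
    the dark-phase activity scaling (smooth 0.5 h transitions at ZT12/ZT24),
    and -- for activity on a given study ``night`` -- the onset gate that
    holds activity at a sub-threshold light-phase level for
    ``effects.onset_delay[night-1]`` hours after lights-off.
    """
    zt = np.asarray(zt, dtype=float) % 24.0
    if group == "nonpregnant" or effects is None or block == 0:
        return profile.curve(zt)
    out = profile.curve(
        zt,
        delays=effects.delays_for(profile.behaviour, block),
        folds=effects.folds_for(profile.behaviour, block),
    )
    if profile.behaviour == "activity":
        s = effects.activity_scale_dark.get(block, 1.0)
        if s < 1.0:
            w = _smoothstep((zt - 12.0) / 0.25) * (1.0 - _smoothstep((zt - 23.7) / 0.3))
            out = out * (1.0 - (1.0 - s) * w)
        if night >= 1:
            gate = effects.night_delay(night)
            # suppress activity until lights-off + gate ...
            if gate > 0:
                light_floor = float(profile.baseline(np.array([8.0]))[0]) * 0.5
                g = _smoothstep((zt - (12.0 + gate)) / 0.25)
                gated = light_floor + (out - light_floor) * g
                out = np.where(zt >= 12.0, np.minimum(out, gated), out)
            # ... then replay the unscaled early-dark activity rise, shifted
            # by the gate: the onset burst the detector keys on.  It decays
            # after ~1.5 h back to the scaled pregnant profile.
            tau = zt - 12.0 - gate
            in_dark = (zt >= 12.0) & (zt < 24.0)
            replay = profile.curve(np.clip(zt - gate, 0.0, 24.0))
            decay = 1.0 - _smoothstep((tau - 1.5) / 1.0)
            burst = replay * decay
            out = np.where(in_dark & (tau >= 0.0), np.maximum(out, burst), out)
    return out
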