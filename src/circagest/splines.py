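"""Natural cubic spline basis on the unwrapped Zeitgeber-time axis.

The circadian axis is unwrapped to ZT6-ZT30 (hours since lights-on, with
ZT0-ZT6 of a calendar day mapped to ZT24-ZT30 of the previous cycle) so that
the knot span ZT8.5-ZT28.5 is interior to the data and the dark phase
(ZT12-ZT24) sits in the middle of the axis.  The default knot vector is 13
knots evenly spaced over that span (spacing 20/12 h).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SplineBasis", "natural_spline_basis", "default_knots", "unwrap_zt", "ZT_GRID_STEP", "zt_grid"]

ZT_GRID_STEP = 0.05


def default_knots() -> np.ndarray:
    """Full knot vector of the circadian basis.

    The 13 evenly spaced knots from ZT8.5 to ZT28.5 (= ZT4.5 of the next
    day) are interior knots, as in R's ``splines::ns(x, knots=...)``; the
    boundary knots sit at the hourly data range (ZT6.5, ZT29.5).  Placing
    the boundary at ZT8.5 instead would force the basis to be linear over
    ZT6-ZT8.5 and it could not represent the late-light behavioural peaks
    around ZT9 that the windowed analysis targets.
    """
    return np.concatenate([[6.5], np.linspace(8.5, 28.5, 13), [29.5]])


def unwrap_zt(zt):
    """Map ZT in [0, 24) to the unwrapped axis [6, 30): hours before ZT6
    belong to the late (early-light) end of the previous cycle."""
    zt = np.asarray(zt, dtype=float)
    return np.where(zt < 6.0, zt + 24.0, zt)


def zt_grid(step: float = ZT_GRID_STEP) -> np.ndarray:
    """Evaluation grid ZT6 -> ZT30 (inclusive) used for posterior curves."""
    n = int(round(24.0 / step))
    return np.round(6.0 + step * np.arange(n + 1), 10)


def natural_spline_basis(x, knots) -> np.ndarray:
    """Natural cubic spline basis (without intercept column).

    Truncated-power construction: with knots ``xi_1 < ... < xi_K`` the
    returned matrix has K-1 columns spanning the space of cubic splines that
    are linear beyond the boundary knots (the same function space as R's
    ``splines::ns`` with the interior knots ``xi_2..xi_{K-1}`` and boundary
    knots ``xi_1, xi_K``; the column parametrisation differs).

    Parameters
    ----------
    x : array-like
        Evaluation points (any real values; linear extrapolation applies
        outside the boundary knots).
    knots : array-like
        Full strictly increasing knot vector, length K >= 3.
    """
    x = np.asarray(x, dtype=float).ravel()
    knots = np.asarray(knots, dtype=float).ravel()
    if knots.size < 3:
        raise ValueError("need at least 3 knots")
    if np.any(np.diff(knots) <= 0):
        raise ValueError("knots must be strictly increasing")
    K = knots.size
    span = knots[-1] - knots[0]
    # scale to unit span for numerical stability of the cubes
    xs = (x - knots[0]) / span
    ks = (knots - knots[0]) / span

    def d(k):  # (x - xi_k)_+^3 - (x - xi_K)_+^3, divided by xi_K - xi_k
        num = np.clip(xs - ks[k], 0.0, None) ** 3 - np.clip(xs - ks[-1], 0.0, None) ** 3
        return num / (ks[-1] - ks[k])

    cols = np.empty((x.size, K - 1))
    cols[:, 0] = xs
    dlast = d(K - 2)
    for k in range(K - 2):
        cols[:, k + 1] = d(k) - dlast
    return cols


@dataclass
class SplineBasis:
    """Basis generator bound to a knot vector (default: the circadian knots).

    ``design`` returns columns orthonormalised (QR) against the 24 hourly
    midpoints ZT6.5..ZT29.5.  This is a fixed, invertible reparametrisation
    of [1, N_1(t), ..., N_{K-1}(t)]: it spans the identical function space
    but keeps coefficients O(1) and well conditioned for the samplers (the
    raw truncated-power columns are nearly collinear).
    """

    knots: np.ndarray = field(default_factory=default_knots)

    def __post_init__(self):
        self.knots = np.asarray(self.knots, dtype=float)
        t_ref = np.sort(unwrap_zt(np.arange(24) + 0.5))
        B = self._raw(t_ref)
        _, R = np.linalg.qr(B)
        self._transform = np.linalg.inv(R) * np.sqrt(len(t_ref))
        if self._transform[0, 0] < 0:  # keep the intercept direction at +1
            self._transform[:, 0] *= -1.0

    @property
    def n_cols(self) -> int:
        return len(self.knots) - 1

    def _raw(self, t) -> np.ndarray:
        B = natural_spline_basis(t, self.knots)
        return np.column_stack([np.ones(B.shape[0]), B])

    def design(self, t) -> np.ndarray:
        """Orthonormalised design columns (intercept direction included)."""
        return self._raw(t) @ self._transform
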