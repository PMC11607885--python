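"""Posterior peak detection within circadian windows."""

import numpy as np
import pytest

from circagest.peaks import detect_peaks_draws, significance
from circagest.profiles import WINDOWS
from circagest.splines import zt_grid

GRID = zt_grid()


def brute_force_peak(curve, window):
    """Exhaustive scan of every grid point (reference oracle)."""
    lo, hi = window
    best = None
    for i in range(1, len(GRID) - 1):
        if not (lo <= GRID[i] < hi):
            continue
        if curve[i] > curve[i - 1] and curve[i] > curve[i + 1]:
            if best is None or curve[i] > curve[best]:
                best = i
    if best is None:
        return False, np.nan, np.nan
    return True, GRID[best], curve[best]


class TestDetect:
    def test_parabola_peak_found_at_vertex(self):
        curve = -((GRID - 13.5) ** 2)
        present, t, a = detect_peaks_draws(curve[None, :], GRID, WINDOWS["II"])
        assert present[0] and t[0] == pytest.approx(13.5) and a[0] == pytest.approx(0.0)

    def test_monotone_curve_has_no_peak(self):
        curve = GRID * 0.1  # strictly increasing over window IV
        present, t, a = detect_peaks_draws(curve[None, :], GRID, WINDOWS["IV"])
        assert not present[0] and np.isnan(t[0])

    def test_largest_of_two_local_maxima_wins(self):
        curve = 0.30 * np.exp(-0.5 * ((GRID - 12.8) / 0.3) ** 2) + 0.35 * np.exp(
            -0.5 * ((GRID - 14.2) / 0.3) ** 2
        )
        present, t, a = detect_peaks_draws(curve[None, :], GRID, WINDOWS["II"])
        assert t[0] == pytest.approx(14.2) and a[0] == pytest.approx(0.35, abs=1e-3)

    def test_tie_breaks_to_earliest_time(self):
        curve = np.zeros_like(GRID)
        for c in (12.5, 14.0):
            curve += np.where(np.abs(GRID - c) <= 0.2, 0.2 - np.abs(GRID - c), 0.0)
        present, t, a = detect_peaks_draws(curve[None, :], GRID, WINDOWS["II"])
        assert t[0] == pytest.approx(12.5)

    def test_matches_exhaustive_scan_on_random_smooth_curves(self):
        rng = np.random.default_rng(99)
        for _ in range(200):  # x 5 windows = 1000 comparisons
            freqs = rng.uniform(0.1, 1.2, 4)
            phases = rng.uniform(0, 2 * np.pi, 4)
            amps = rng.uniform(0.2, 1.0, 4)
            curve = sum(a * np.sin(2 * np.pi * f * GRID / 24 + p) for a, f, p in zip(amps, freqs, phases))
            for wid, window in WINDOWS.items():
                present, t, a = detect_peaks_draws(curve[None, :], GRID, window)
                bp, bt, ba = brute_force_peak(curve, window)
                assert present[0] == bp
                if bp:
                    assert t[0] == bt and a[0] == ba

    def test_presence_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(5)
        draws = np.cumsum(rng.standard_normal((50, len(GRID))) * 0.05, axis=1) + 2.5
        for window in WINDOWS.values():
            p1, _, _ = detect_peaks_draws(draws, GRID, window)
            p2, _, _ = detect_peaks_draws(np.exp(draws), GRID, window)
            assert np.array_equal(p1, p2)

    def test_reported_times_lie_inside_window(self):
        rng = np.random.default_rng(6)
        draws = np.cumsum(rng.standard_normal((200, len(GRID))) * 0.05, axis=1)
        for (lo, hi) in WINDOWS.values():
            present, t, _ = detect_peaks_draws(draws, GRID, (lo, hi))
            assert np.all((t[present] >= lo) & (t[present] < hi))

    def test_uncovered_window_rejected(self):
        with pytest.raises(ValueError):
            detect_peaks_draws(np.zeros((1, 10)), GRID[:10], WINDOWS["V"])


class TestSignificance:
    @pytest.mark.parametrize(
        "interval, expect",
        [
            ((0.70, 2.22), True),    # delayed window-I food peak, mid-pregnancy
            ((-0.90, 0.58), False),  # the same contrast in early pregnancy
            ((0.0, 1.0), False),     # an endpoint at zero counts as crossing
            ((-2.0, -0.1), True),
        ],
    )
    def test_interval_rule(self, interval, expect):
        assert significance(interval) is expect

    def test_nan_endpoint_rejected(self):
        with pytest.raises(ValueError):
            significance((np.nan, 1.0))


class TestSummaries:
    def make_curves(self, np_curves, p_curves):
        from circagest.model import PosteriorCurves

        draws = {("nonpregnant", 1): np_curves, ("pregnant", 1): p_curves}
        return PosteriorCurves(
            behaviour="food", zt_grid=GRID, draws=draws, link_draws=draws,
            sigma2=np.zeros(np_curves.shape[0]), rhat_max=1.0, converged=True,
        )

    def bump(self, centre, height=1.0):
        return height * np.exp(-0.5 * ((GRID - centre) / 0.5) ** 2)

    def test_presence_share(self):
        from circagest.peaks import summarise

        np_d = np.stack([self.bump(13.5), self.bump(13.5), self.bump(13.5), GRID * 0.01])
        p_d = np.stack([self.bump(13.5)] * 4)
        s = summarise(self.make_curves(np_d, p_d), 1, "II")
        assert s.presence["nonpregnant"] == pytest.approx(75.0)
        assert s.presence["pregnant"] == pytest.approx(100.0)

    def test_constant_shift_gives_degenerate_difference_interval(self):
        from circagest.peaks import summarise

        np_d = np.stack([self.bump(13.0)] * 8)
        p_d = np.stack([self.bump(14.0)] * 8)
        s = summarise(self.make_curves(np_d, p_d), 1, "II")
        st = s.stats.set_index(["quantity", "series"])
        row = st.loc[("time", "difference")]
        assert row["mean"] == pytest.approx(1.0)
        assert row["lo2.5"] == pytest.approx(1.0) and row["hi97.5"] == pytest.approx(1.0)
        assert row["significant"] == True  # noqa: E712

    def test_difference_undefined_when_joint_presence_rare(self):
        from circagest.peaks import summarise

        np_d = np.stack([GRID * 0.01] * 8)  # never a peak
        p_d = np.stack([self.bump(13.5)] * 8)
        s = summarise(self.make_curves(np_d, p_d), 1, "II")
        assert s.note is not None and "undefined" in s.note

    def test_flagged_fit_refused_without_force(self):
        from circagest.peaks import summarise

        c = self.make_curves(np.stack([self.bump(13.5)]), np.stack([self.bump(13.5)]))
        c.converged = False
        with pytest.raises(RuntimeError):
            summarise(c, 1, "II")
        summarise(c, 1, "II", force=True)  # no raise
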