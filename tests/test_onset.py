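"""Dark-phase activity-onset detection and the group mixed model."""

import numpy as np
import pandas as pd
import pytest

from circagest.onset import (
    BLOCK_H,
    acclimation_threshold,
    detect_onset,
    onset_group_model,
    onsets_by_night,
    validate_acclimation,
)


def zt_blocks(n=144):
    return 12.0 + BLOCK_H * np.arange(n)


def brute_force_onset(values, threshold):
    """Exhaustive scan over all candidate run starts (reference oracle)."""
    above = np.asarray(values) > threshold
    for i in range(len(above) - 2):
        if above[i] and above[i + 1] and above[i + 2]:
            return i * BLOCK_H, False
    return 12.0, True


class TestDetectOnset:
    def test_run_starting_at_third_block(self):
        values = [0, 2, 6, 6, 6] + [0] * 139
        onset, cens = detect_onset(zt_blocks(), values, 5.0)
        assert onset == pytest.approx(10 / 60)
        assert not cens

    def test_interrupted_run_restarts(self):
        values = [6, 6, 4, 6, 6, 6] + [0] * 138
        onset, cens = detect_onset(zt_blocks(), values, 5.0)
        assert onset == pytest.approx(0.25)

    def test_never_above_threshold_censors_at_12h(self):
        onset, cens = detect_onset(zt_blocks(), np.full(144, 5.0), 5.0)  # ties don't trigger
        assert onset == 12.0 and cens

    def test_gap_in_blocks_breaks_runs(self):
        zt = np.array([12.0, 12.0 + BLOCK_H, 12.0 + 3 * BLOCK_H, 12.0 + 4 * BLOCK_H, 12.0 + 5 * BLOCK_H])
        values = np.array([6.0, 6.0, 6.0, 6.0, 6.0])
        onset, cens = detect_onset(zt, values, 5.0)
        # blocks 0-1 then a gap: first full run starts at the 3rd present block
        assert onset == pytest.approx(3 * BLOCK_H)

    def test_matches_exhaustive_scan_on_random_traces(self):
        rng = np.random.default_rng(123)
        zt = zt_blocks()
        for _ in range(1000):
            values = rng.gamma(1.0, 2.0, size=144)
            thr = rng.uniform(0.5, 6.0)
            assert detect_onset(zt, values, thr) == brute_force_onset(values, thr)

    def test_onset_monotone_in_threshold(self):
        rng = np.random.default_rng(7)
        zt = zt_blocks()
        for _ in range(200):
            values = rng.gamma(1.0, 2.0, size=144)
            onsets = [detect_onset(zt, values, t)[0] for t in (0.5, 1.5, 3.0, 5.0)]
            assert onsets == sorted(onsets)

    def test_censoring_rate_non_decreasing_in_threshold(self):
        rng = np.random.default_rng(8)
        zt = zt_blocks()
        traces = rng.gamma(1.0, 2.0, size=(100, 144))
        rates = []
        for thr in (0.5, 2.0, 4.0, 8.0):
            rates.append(np.mean([detect_onset(zt, v, thr)[1] for v in traces]))
        assert rates == sorted(rates)


class TestThreshold:
    def test_mean_of_acclimation_dark_blocks(self):
        df = pd.DataFrame(
            {
                "mouse_id": "m", "group": "nonpregnant",
                "day": [-1.6, -1.55, -1.5, -1.2],
                "zt_start": [12.0, 13.0, 14.0, 8.0],  # last one is light phase
                "behaviour": "activity",
                "value": [2.0, 4.0, 6.0, 99.0],
            }
        )
        thr = acclimation_threshold(df)
        assert thr["threshold"].iloc[0] == pytest.approx(4.0)

    def test_zero_activity_gives_zero_threshold(self):
        df = pd.DataFrame(
            {"mouse_id": "m", "group": "nonpregnant", "day": [-1.6] * 3,
             "zt_start": [12.0, 13.0, 14.0], "behaviour": "activity", "value": [0.0] * 3}
        )
        assert acclimation_threshold(df)["threshold"].iloc[0] == 0.0

    def test_no_acclimation_data_raises(self):
        df = pd.DataFrame(
            {"mouse_id": "m", "group": "nonpregnant", "day": [1.6],
             "zt_start": [12.0], "behaviour": "activity", "value": [1.0]}
        )
        with pytest.raises(ValueError):
            acclimation_threshold(df)

    def test_threshold_matches_generator_dark_mean(self, small_blocks):
        """On synthetic data the per-mouse threshold approximates the
        profile's dark-phase mean per 5-min block."""
        from circagest.profiles import default_profiles

        prof = default_profiles()["activity"]
        zt = np.arange(12, 24, 1 / 12)
        expect = prof.curve(zt).mean() / 12
        thr = acclimation_threshold(small_blocks)
        assert np.allclose(thr["threshold"], expect, rtol=0.25)


class TestValidation:
    def test_share_within_two_hours(self):
        ons = pd.DataFrame({"mouse_id": list("abcd"), "onset": [0.5, 1.0, 3.0, 1.5]})
        assert validate_acclimation(ons)["fraction_nights"] == 0.75

    def test_all_censored_gives_zero(self):
        ons = pd.DataFrame({"mouse_id": list("ab"), "onset": [12.0, 12.0]})
        v = validate_acclimation(ons)
        assert v["fraction_nights"] == 0.0 and v["fraction_mice"] == 0.0

    def test_default_cohort_acclimation_mostly_prompt(self, small_blocks):
        ons = onsets_by_night(small_blocks)
        v = validate_acclimation(ons[ons["phase"] == "acclimation"])
        assert v["fraction_nights"] >= 0.95
        assert v["fraction_mice"] == 1.0


def synthetic_onsets(shift=0.0, n=4, nights=6, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for g, base in (("nonpregnant", 1.0), ("pregnant", 1.0 + shift)):
        for i in range(n):
            for d in range(1, nights + 1):
                rows.append(
                    {"mouse_id": f"{g[:2]}{i}", "group": g, "night": d, "phase": "study",
                     "onset": base + 0.1 * d + noise * rng.standard_normal(), "censored": False}
                )
    return pd.DataFrame(rows)


class TestGroupModel:
    def test_identical_onset_series_give_zero_differences(self):
        """Exactly identical onset series in both groups: all per-night
        differences are zero and the interaction is null (the degenerate
        zero-variance fit is reported as non-converged, not dropped)."""
        res = onset_group_model(synthetic_onsets(0.0, noise=0.0))
        assert np.allclose(res.per_day["difference"], 0.0, atol=1e-10)
        assert res.interaction_p > 0.99

    def test_constant_shift_recovered_each_day_without_interaction(self):
        res = onset_group_model(synthetic_onsets(2.0, noise=0.05, seed=2))
        assert np.allclose(res.per_day["difference"], 2.0, atol=0.15)
        assert res.interaction_p > 0.05
        assert (res.per_day["p"] < 0.01).all()

    def test_balanced_complete_equals_cell_mean_differences(self):
        df = synthetic_onsets(1.0, noise=0.3, seed=3)
        res = onset_group_model(df)
        cell = df.groupby(["group", "night"])["onset"].mean().unstack(0)
        expect = (cell["pregnant"] - cell["nonpregnant"]).values
        got = res.per_day.sort_values("night")["difference"].values
        assert np.allclose(got, expect, atol=1e-4)

    def test_needs_two_mice_per_group(self):
        df = synthetic_onsets(0.0)
        df = df[~((df["group"] == "pregnant") & (df["mouse_id"] != "pr0"))]
        with pytest.raises(ValueError):
            onset_group_model(df)
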