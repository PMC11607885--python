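"""Synthetic-cohort generator: ground truth, noise model, reproducibility."""

import numpy as np
import pandas as pd
import pytest

from circagest.cohort import generate_cohort, inject_truth_log, read_cohort, write_cohort
from circagest.profiles import (
    BehaviourProfileSpec,
    CohortConfig,
    PeakSpec,
    PregnancyEffectSpec,
    default_effects,
    default_profiles,
)

from conftest import small_config


def flat_profile(behaviour="food", level=0.12, peaks=(), **kw):
    return BehaviourProfileSpec(
        behaviour, baseline_points=[(0, level), (8, level), (16, level)], peaks=list(peaks), **kw
    )


def test_degenerate_noise_reproduces_flat_level_exactly():
    """Zero noise, zero intercepts, flat baseline: every record equals the
    per-interval share of the hourly level."""
    cfg = small_config(n=2, seed=1)
    profs = {"food": flat_profile()}
    rec = generate_cohort(cfg, profs, PregnancyEffectSpec(onset_delay=np.zeros(17)))
    assert np.allclose(rec["value"], 0.12 / 12, atol=1e-12)


def test_beta_concentration_limit():
    """With precision -> 1e6 generated wake fractions converge to the mean."""
    cfg = small_config(n=2, seed=2)
    profs = {"wake": flat_profile("wake", 0.4, beta_precision=1e6)}
    rec = generate_cohort(cfg, profs, PregnancyEffectSpec(onset_delay=np.zeros(17)))
    assert np.max(np.abs(rec["value"] - 0.4)) < 1e-2


def test_wake_hourly_mean_matches_profile_within_monte_carlo_error():
    cfg = small_config(n=2, seed=3)
    profs = {"wake": flat_profile("wake", 0.35, beta_precision=40.0)}
    rec = generate_cohort(cfg, profs, PregnancyEffectSpec(onset_delay=np.zeros(17)))
    n = len(rec)
    se = np.sqrt(0.35 * 0.65 / 41.0 / n)
    assert abs(rec["value"].mean() - 0.35) < 3 * se
    assert n >= 200


def test_fixed_seed_is_bit_reproducible():
    a = generate_cohort(small_config(n=2, seed=5))
    b = generate_cohort(small_config(n=2, seed=5))
    pd.testing.assert_frame_equal(a, b)


def test_seed_is_mandatory():
    cfg = small_config(n=2, seed=0)
    cfg.random_seed = None
    with pytest.raises(ValueError, match="seed"):
        generate_cohort(cfg)


def test_invalid_counts_and_schedule_rejected():
    with pytest.raises(ValueError):
        CohortConfig(n_nonpregnant=0, random_seed=1)
    with pytest.raises(ValueError):
        CohortConfig(
            termination_schedule={"nonpregnant": (1, 1, 1), "pregnant": (10, 10, 11)},
            random_seed=1,
        )
    with pytest.raises(ValueError):
        CohortConfig(sampling_interval=700, random_seed=1)


def test_termination_truncates_records_at_block_boundaries():
    rec = generate_cohort(CohortConfig(random_seed=9))
    last = rec[rec["group"] == "pregnant"].groupby("mouse_id")["day"].max()
    ends = np.sort(np.round(last.values + 300 / 86400, 3))
    # default pregnant schedule: 10 to day 6.5, 10 to 12.5, 11 to 17.5
    assert list(ends) == [6.5] * 10 + [12.5] * 10 + [17.5] * 11


def test_default_food_profile_is_nocturnally_biased():
    """The noise-free default food profile concentrates 65-80% of the daily
    integral in the dark phase, as expected of nocturnal rodents."""
    profs = default_profiles()
    assert 0.65 <= profs["food"].dark_fraction() <= 0.80
    for name, p in profs.items():
        zt = np.arange(0, 24, 0.05)
        v = p.curve(zt)
        assert v[(zt >= 12)].mean() > v[(zt < 12)].mean()


def test_peak_times_must_lie_inside_their_window():
    with pytest.raises(ValueError):
        PeakSpec("I", 13.0, 1.0)
    with pytest.raises(ValueError):
        BehaviourProfileSpec("wake", baseline_points=[(0, 1.2), (12, 0.5)])


class TestTruthLog:
    def cfg_profiles(self):
        profs = {
            "food": flat_profile(
                "food", 0.05,
                peaks=[PeakSpec("I", 9.0, 0.2, width=0.8), PeakSpec("II", 13.5, 0.3, width=0.8)],
            )
        }
        return small_config(n=2, seed=4), profs

    def test_no_effects_gives_zero_differences(self):
        cfg, profs = self.cfg_profiles()
        truth = inject_truth_log(cfg, profs, PregnancyEffectSpec(onset_delay=np.zeros(17)))
        t = truth[truth["behaviour"] == "food"].dropna(subset=["time_diff"])
        assert np.allclose(t["time_diff"], 0.0)
        assert np.allclose(t["amp_diff"], 0.0)

    def test_peak_delay_echoes_into_truth(self):
        """On a flat baseline a 1.5 h window-I delay is echoed exactly."""
        cfg, profs = self.cfg_profiles()
        eff = PregnancyEffectSpec(
            peak_delay={2: {("food", "I"): 1.5}}, onset_delay=np.zeros(17)
        )
        truth = inject_truth_log(cfg, profs, eff)
        row = truth[(truth.behaviour == "food") & (truth.block == 2) & (truth.window == "I")].iloc[0]
        assert row["time_diff"] == pytest.approx(1.5, abs=0.011)
        row1 = truth[(truth.behaviour == "food") & (truth.block == 1) & (truth.window == "I")].iloc[0]
        assert row1["time_diff"] == pytest.approx(0.0, abs=0.011)

    def test_amplitude_fold_echoes_into_truth(self):
        """A x2 fold on the window-II bump doubles the bump height above the
        flat baseline."""
        cfg, profs = self.cfg_profiles()
        eff = PregnancyEffectSpec(
            amplitude_fold={2: {("food", "II"): 2.0}}, onset_delay=np.zeros(17)
        )
        truth = inject_truth_log(cfg, profs, eff)
        row = truth[(truth.behaviour == "food") & (truth.block == 2) & (truth.window == "II")].iloc[0]
        assert (row["amp_pregnant"] - 0.05) / (row["amp_nonpregnant"] - 0.05) == pytest.approx(2.0, rel=1e-3)

    def test_onset_delays_echo(self):
        cfg, profs = self.cfg_profiles()
        ramp = np.linspace(0, 6, 17)
        eff = PregnancyEffectSpec(onset_delay=ramp)
        truth = inject_truth_log(cfg, profs, eff)
        ons = truth[truth["behaviour"] == "onset"].sort_values("window", key=lambda s: s.str[5:].astype(int))
        assert np.allclose(ons["time_diff"].values, ramp)


def test_csv_round_trip(tmp_path):
    rec = generate_cohort(small_config(n=2, seed=6))
    path = tmp_path / "raw.csv"
    write_cohort(rec, path)
    back = read_cohort(path)
    assert list(back.columns) == ["mouse_id", "group", "day", "zt_hour", "behaviour", "value"]
    assert len(back) == len(rec)
    with pytest.raises(ValueError, match="missing columns"):
        bad = tmp_path / "bad.csv"
        rec[["mouse_id", "day"]].to_csv(bad, index=False)
        read_cohort(bad)
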