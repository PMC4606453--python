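"""Sleep scoring: rebinning, bout detection, epoch summaries, heat-shock ratio."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from larvasleep.errors import AnalysisError
from larvasleep.io_tracking import ActivityMatrix, EpochSchedule, PlateMap
from larvasleep.sleep_metrics import (
    SleepBout,
    detect_sleep_bouts,
    heat_shock_sleep_change,
    rebin,
    summarize_epoch,
    summarize_all,
)
from larvasleep.synthetic_data import EpochSleepParams, SleepSimParams, simulate_sleep_wake

from conftest import minute_matrix


def brute_force_bouts(values):
    """Independent run-length oracle: linear scan for maximal zero runs."""
    bouts, start = [], None
    for i, v in enumerate(values):
        if v == 0 and start is None:
            start = i
        elif v != 0 and start is not None:
            bouts.append((start, i - start))
            start = None
    if start is not None:
        bouts.append((start, len(values) - start))
    return bouts


def ten_min_schedule():
    """Toy schedule whose 'day' epoch is exactly the first 10 minutes."""
    return EpochSchedule(lights_on="00:00", lights_off="00:10", experiment_start="00:00")


class TestRebin:
    def test_six_10s_bins_sum_to_one_minute(self):
        m = ActivityMatrix(("a",), np.arange(6) * 10.0, 10.0, [[1, 0, 2, 0, 0, 3]])
        out = rebin(m, 60.0)
        assert out.values.tolist() == [[6.0]] and out.bin_width == 60.0

    def test_identity_when_widths_equal(self):
        m = minute_matrix([1, 2, 3])
        assert rebin(m, 60.0) is m

    def test_non_multiple_width_rejected(self):
        with pytest.raises(AnalysisError, match="integer multiple"):
            rebin(minute_matrix([1, 2]), 90.0)

    @given(st.integers(0, 2**31 - 1))
    def test_total_activity_conserved(self, seed):
        rng = np.random.default_rng(seed)
        m = ActivityMatrix(
            ("a", "b"), np.arange(12) * 10.0, 10.0, rng.uniform(0, 10, (2, 12))
        )
        assert np.isclose(rebin(m, 60.0).values.sum(), m.values.sum())


class TestBoutDetection:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([0, 0, 0, 5, 0], [(0, 3), (4, 1)]),
            ([1, 2, 3], []),
            ([0], [(0, 1)]),
            ([5, 0, 0], [(1, 2)]),
        ],
    )
    def test_examples(self, values, expected):
        assert [(b.start_bin, b.duration) for b in detect_sleep_bouts(values)] == expected

    def test_equals_brute_force_on_random_binary_traces(self, rng):
        for _ in range(1000):
            v = rng.integers(0, 2, size=rng.integers(1, 40)).astype(float)
            got = [(b.start_bin, b.duration) for b in detect_sleep_bouts(v)]
            assert got == brute_force_bouts(v)

    def test_bout_duration_must_be_positive(self):
        with pytest.raises(Exception):
            SleepBout(0, 0)


class TestSummarizeEpoch:
    def test_all_zero_epoch(self):
        m = minute_matrix([0] * 10)
        s = summarize_epoch(m, ten_min_schedule(), "day4", "L001")
        assert s.sleep == 10 and s.bout_count == 1 and s.sleep_latency == 0
        assert s.waking_activity == 0 and not s.waking_defined and not s.latency_censored

    def test_never_zero_epoch_censors_latency(self):
        m = minute_matrix([1] * 10)
        s = summarize_epoch(m, ten_min_schedule(), "day4", "L001")
        assert s.sleep == 0 and s.bout_count == 0
        assert s.sleep_latency == 10 and s.latency_censored

    def test_hand_computed_toy_epoch(self):
        # values [3,0,0,4,0,0,0,2,5,0]: sleep 6, bouts 3, mean 2, latency 1,
        # total activity 14, waking activity 14/4
        m = minute_matrix([3, 0, 0, 4, 0, 0, 0, 2, 5, 0])
        s = summarize_epoch(m, ten_min_schedule(), "day4", "L001")
        assert s.sleep == 6 and s.bout_count == 3 and s.mean_bout_length == 2
        assert s.sleep_latency == 1 and s.total_activity == 14
        assert s.waking_activity == pytest.approx(14 / 4)

    def test_non_minute_bins_direct_to_rebin(self):
        m = ActivityMatrix(("a",), np.arange(60) * 10.0, 10.0, np.ones((1, 60)))
        with pytest.raises(AnalysisError, match="rebin"):
            summarize_epoch(m, ten_min_schedule(), "day4", "a")

    def test_epoch_beyond_data_rejected(self):
        m = minute_matrix([0] * 5)  # 5 min of data for a 10-min epoch
        with pytest.raises(AnalysisError, match="beyond the recording"):
            summarize_epoch(m, ten_min_schedule(), "day4", "L001")

    def test_sleep_plus_wake_conservation_random(self, rng, schedule):
        """sleep + waking minutes = epoch minutes on 1000 random day traces."""
        n_min = 14 * 60
        for _ in range(1000):
            v = rng.integers(0, 2, n_min) * rng.uniform(0, 60, n_min)
            s = summarize_epoch(minute_matrix(v), schedule, "day4", "L001")
            waking = n_min - s.sleep
            assert s.sleep + waking == n_min
            assert np.isclose(s.waking_activity * waking, s.total_activity)
            assert np.isclose(s.mean_bout_length * s.bout_count, s.sleep)
            assert 0 <= s.sleep_latency <= n_min

    def test_boundary_spanning_bout_split_between_epochs(self, schedule):
        # zeros straddling the day4/night4 boundary (minute 840)
        v = np.ones(15 * 60)
        v[835:845] = 0.0
        m = minute_matrix(v)
        day = summarize_epoch(m, schedule, "day4", "L001")
        assert day.sleep == 5 and day.bout_count == 1

    def test_invariant_to_chunk_concatenation(self, rng, schedule):
        """Summaries agree whether computed from one long recording or from
        the same data with extra context before/after the epoch."""
        v = rng.integers(0, 2, 24 * 60) * rng.uniform(0, 60, 24 * 60)
        m_full = minute_matrix(v)
        m_day = minute_matrix(v[: 14 * 60])
        a = summarize_epoch(m_full, schedule, "day4", "L001")
        b = summarize_epoch(m_day, schedule, "day4", "L001")
        assert a == b


class TestHeatShockRatio:
    def _summaries(self, pre, post):
        rows = []
        for i, (a, b) in enumerate(zip(pre, post)):
            rows.append({"larva_id": f"L{i}", "epoch": "night5", "sleep": a})
            rows.append({"larva_id": f"L{i}", "epoch": "night6", "sleep": b})
        return pd.DataFrame(rows)

    def test_no_change_is_100_percent(self):
        df = self._summaries([100, 120], [100, 120])
        out = heat_shock_sleep_change(df, "night5", "night6", {"L0": "wt", "L1": "wt"})
        # genotype mean pre = 110; 100/110 and 120/110
        assert np.allclose(out["sleep_change_pct"], [100 / 1.1, 120 / 1.1])

    def test_forced_by_formula(self):
        df = self._summaries([200, 200], [80, 80])
        out = heat_shock_sleep_change(df, "night5", "night6", {"L0": "g", "L1": "g"})
        assert np.allclose(out["sleep_change_pct"], 40.0)

    def test_zero_pre_sleep_is_error(self):
        df = self._summaries([0, 0], [10, 10])
        with pytest.raises(AnalysisError, match="zero mean pre-night sleep"):
            heat_shock_sleep_change(df, "night5", "night6", {"L0": "g", "L1": "g"})

    def test_planted_ratio_recovered_in_simulation(self):
        """Cohort with night-6 sleep fraction planted at 75% of night 5."""
        sched = EpochSchedule(experiment_start="23:00", start_day=5)
        night5 = EpochSleepParams(8.0, 4.0, 6.0)  # sleep fraction 1/3
        night6 = EpochSleepParams(12.0, 3.0, 6.0)  # fraction 0.2 = 0.75 * (1/3) * 0.8...
        # fractions: 4/12 = 1/3 and 3/15 = 1/5; ratio = 0.6
        params = SleepSimParams(
            n_larvae=96,
            duration_h=48.0,
            schedule=sched,
            overrides={"night5": night5, "night6": night6},
            seed=11,
        )
        m = simulate_sleep_wake(params)
        summaries = summarize_all(m, sched, ["night5", "night6"])
        out = heat_shock_sleep_change(
            summaries, "night5", "night6", {l: "wt" for l in m.larva_ids}
        )
        expected = 100.0 * (3 / 15) / (4 / 12)
        sem = out["sleep_change_pct"].std(ddof=1) / np.sqrt(len(out))
        assert abs(out["sleep_change_pct"].mean() - expected) < 3 * sem + 2.0


class TestParameterRecovery:
    def test_night_bout_structure_recovered(self):
        """Planted night bout rate and mean bout length recovered within 5%
        at 96 larvae x 10 h."""
        sched = EpochSchedule(experiment_start="23:00", start_day=5)
        params = SleepSimParams(
            night=EpochSleepParams(8.0, 4.0, 6.0),
            n_larvae=96,
            duration_h=10.0,
            schedule=sched,
            seed=7,
        )
        m = simulate_sleep_wake(params)
        df = summarize_all(m, sched, ["night5"])
        mean_bout = df["sleep"].sum() / df["bout_count"].sum()
        bouts_per_hour = df["bout_count"].sum() / (len(df) * 10.0)
        assert abs(mean_bout - 4.0) / 4.0 < 0.05
        assert abs(bouts_per_hour - 5.0) / 5.0 < 0.05
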