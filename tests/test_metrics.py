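"""Session metrics, group summaries, statistics, and the packaged tables."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vretsim import (
    FixtureError,
    fixture_frames,
    load_fixture_tables,
    one_way_anova,
    pearson,
    summarize,
    window_metrics,
)


def counting_oracle(seg, lo, hi, rate=100.0):
    """Independent per-sample counting implementation of the durations."""
    inside = sum(1 for v in seg if lo <= v <= hi)
    above = sum(1 for v in seg if v > hi)
    below = sum(1 for v in seg if v < lo)
    first = next((i for i, v in enumerate(seg) if lo <= v <= hi), None)
    return (
        inside / rate,
        above / rate,
        below / rate,
        None if first is None else first / rate,
    )


class TestWindowMetrics:
    def test_constant_in_band_window(self):
        m = window_metrics(np.full(6000, 0.75), (0.7, 0.8))
        assert (m.maintenance, m.less_anxious, m.more_anxious) == (60.0, 0.0, 0.0)
        assert m.entrance_time == 0.0

    def test_piecewise_entry_from_above(self):
        seg = np.concatenate([np.full(1000, 0.9), np.full(5000, 0.75)])
        m = window_metrics(seg, (0.7, 0.8))
        assert m.entrance_time == pytest.approx(10.0)
        assert m.less_anxious == pytest.approx(10.0)
        assert m.maintenance == pytest.approx(50.0)

    def test_durations_partition_the_window(self, rng):
        seg = rng.uniform(0.3, 1.1, size=6000)
        m = window_metrics(seg, (0.7, 0.8))
        assert m.maintenance + m.less_anxious + m.more_anxious == pytest.approx(60.0)

    def test_matches_counting_oracle_on_random_step_traces(self, rng):
        for _ in range(20):
            # random piecewise-constant trace
            levels = rng.uniform(0.2, 1.1, size=8)
            seg = np.repeat(levels, rng.integers(50, 400, size=8))
            m = window_metrics(seg, (0.4, 0.5), rate=100.0)
            maint, less, more, ent = counting_oracle(seg, 0.4, 0.5)
            assert m.maintenance == maint
            assert m.less_anxious == less
            assert m.more_anxious == more
            assert m.entrance_time == ent

    def test_recovery_duration_first_rest_band_reentry(self):
        seg = np.full(600, 0.45)
        rest = np.concatenate([np.linspace(0.5, 0.91, 500), np.full(100, 0.95)])
        m = window_metrics(seg, (0.4, 0.5), rest_segment=rest)
        assert m.recovery_duration == pytest.approx(5.0)

    def test_never_recovered_is_none(self):
        m = window_metrics(
            np.full(100, 0.45), (0.4, 0.5), rest_segment=np.full(100, 0.6)
        )
        assert m.recovery_duration is None

    def test_band_never_reached_entrance_none(self):
        m = window_metrics(np.full(100, 0.95), (0.4, 0.5))
        assert m.entrance_time is None
        assert m.maintenance == 0.0

    def test_empty_segment_rejected(self):
        with pytest.raises(ValueError):
            window_metrics(np.array([]), (0.4, 0.5))


class TestSummarize:
    def test_single_value(self):
        s = summarize([42.0])
        assert (s.mean, s.sd) == (42.0, 0.0)
        assert s.occupancy_percent == pytest.approx(70.0)

    def test_occupancy_relation(self, rng):
        vals = rng.uniform(0, 60, 18)
        s = summarize(vals)
        assert s.occupancy_percent == pytest.approx(100 * s.mean / 60)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize([])


class TestAnova:
    def test_identical_groups_give_zero_f(self):
        r = one_way_anova([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.F == pytest.approx(0.0)
        assert (r.df_between, r.df_within) == (1, 4)

    def test_hand_computed_example(self):
        # SSB = 4, SSW = 1, df = (1, 2) -> F = 8
        r = one_way_anova([0.0, 1.0], [2.0, 3.0])
        assert r.F == pytest.approx(8.0)
        assert (r.df_between, r.df_within) == (1, 2)

    def test_matches_textbook_formula_on_random_inputs(self, rng):
        for _ in range(25):
            a = rng.normal(10, 3, size=rng.integers(3, 30))
            b = rng.normal(12, 2, size=rng.integers(3, 30))
            r = one_way_anova(a, b)
            # independent textbook sums-of-squares implementation
            grand = np.concatenate([a, b]).mean()
            ssb = len(a) * (a.mean() - grand) ** 2 + len(b) * (b.mean() - grand) ** 2
            ssw = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
            f_oracle = (ssb / 1) / (ssw / (len(a) + len(b) - 2))
            assert r.F == pytest.approx(f_oracle, abs=1e-9, rel=1e-9)

    def test_zero_within_variance_flagged_infinite(self):
        r = one_way_anova([1.0, 1.0], [2.0, 2.0])
        assert r.degenerate
        assert r.F == float("inf")

    def test_groups_too_small_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova([1.0], [2.0, 3.0])


class TestPearson:
    def test_perfect_correlations(self):
        x = [1.0, 2.0, 3.0, 5.0]
        assert pearson(x, x) == pytest.approx(1.0)
        assert pearson(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_matches_bruteforce_covariance_formula(self, rng):
        x = rng.normal(size=40)
        y = rng.normal(size=40)
        num = ((x - x.mean()) * (y - y.mean())).sum()
        den = np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        assert pearson(x, y) == pytest.approx(num / den, abs=1e-9)

    def test_zero_variance_flagged(self):
        with pytest.raises(ValueError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestFixtureTables:
    def test_record_count(self):
        df = load_fixture_tables()
        assert len(df) == 72  # 18 participants x 2 groups x 2 states

    def test_known_cells(self):
        df = load_fixture_tables()
        exp18 = df[
            (df.group == "experimental") & (df.participant == 18) & (df.state == "LOW")
        ].iloc[0]
        assert exp18.maintenance == pytest.approx(43.40)
        ctl10 = df[
            (df.group == "control") & (df.participant == 10) & (df.state == "HIGH")
        ].iloc[0]
        assert ctl10.more_anxious == 0.0

    def test_experimental_low_summary_cells(self):
        df = fixture_frames()["experimental"]
        s = summarize(df["state1_maintenance"])
        assert s.mean == pytest.approx(44.55, abs=0.005)
        assert s.sd == pytest.approx(6.94, abs=0.01)
        assert s.occupancy_percent == pytest.approx(74.25, abs=0.01)

    def test_control_summary_cells(self):
        ctl = fixture_frames()["control"]
        assert summarize(ctl["state1_maintenance"]).mean == pytest.approx(27.55, abs=0.005)
        s2 = summarize(ctl["state2_maintenance"])
        assert s2.mean == pytest.approx(16.61, abs=0.006)
        # the published 27.68% derives from the rounded mean (16.61/60);
        # the column itself gives 27.69, one rounding ulp away
        assert s2.occupancy_percent == pytest.approx(27.68, abs=0.02)

    def test_population_sd_convention_not_sample(self):
        col = fixture_frames()["experimental"]["state1_maintenance"].to_numpy()
        assert col.std(ddof=0) == pytest.approx(6.94, abs=0.01)  # matches
        assert col.std(ddof=1) == pytest.approx(7.13, abs=0.01)  # would not

    def test_checksum_mismatch_raises(self, monkeypatch):
        import vretsim.metrics as M

        monkeypatch.setitem(
            M._FIXTURES, "experimental", ("experimental_group.csv", "0" * 64)
        )
        with pytest.raises(FixtureError, match="corrupt"):
            fixture_frames()
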