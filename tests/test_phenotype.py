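"""Sleep scoring, death censoring, anticipation, actograms, periodogram, CTCF."""

import numpy as np
import pandas as pd
import pytest

from tadakit.phenotype import (
    ActivitySeries,
    actogram_matrix,
    anticipation_index,
    behavior_summary,
    censor_at_death,
    chi_square_periodogram,
    ctcf,
    detect_death,
    parse_dam_file,
    percent_rhythmic,
    resample_to_5min,
    score_sleep,
)
from tadakit.synthetic import gen_dam_series, write_dam_file


def _series(counts, bin_minutes=5):
    return ActivitySeries("f", bin_minutes, np.asarray(counts))


class TestDamParsing:
    def test_round_trip(self, tmp_path):
        series, _ = gen_dam_series(n_flies=3, days=2, seed=0)
        path = tmp_path / "Monitor1.txt"
        write_dam_file(series, path)
        back = parse_dam_file(path, bin_minutes=5)
        assert len(back) == 32
        for i in range(3):
            assert (back[i].counts == series[i].counts).all()
        assert (back[5].counts == 0).all()  # unused channel

    def test_status_row_excluded(self, tmp_path):
        series, _ = gen_dam_series(n_flies=1, days=1, seed=0)
        path = tmp_path / "m.txt"
        write_dam_file(series, path)
        lines = path.read_text().splitlines(keepends=True)
        f = lines[3].split("\t")
        f[3] = "51"
        lines[3] = "\t".join(f)
        back = parse_dam_file(lines, bin_minutes=5)
        assert len(back[0].counts) == len(series[0].counts) - 1

    def test_timestamp_gap_is_error(self, tmp_path):
        series, _ = gen_dam_series(n_flies=1, days=1, seed=0)
        path = tmp_path / "m.txt"
        write_dam_file(series, path)
        lines = path.read_text().splitlines(keepends=True)
        del lines[5]
        with pytest.raises(ValueError, match="gap"):
            parse_dam_file(lines, bin_minutes=5)

    def test_malformed_row_names_line(self):
        with pytest.raises(ValueError, match="line 1"):
            parse_dam_file(["garbage\trow\n"], bin_minutes=5)


class TestDeath:
    def test_terminal_25h_zero_run(self):
        active = [3] * 288
        dead = [0] * (25 * 12)
        s = _series(active + dead)
        assert detect_death(s) == 288

    def test_mid_series_immobility_is_not_death(self):
        s = _series([3] * 288 + [0] * (25 * 12) + [3] * 288)
        assert detect_death(s) is None
        # unless the anywhere rule is requested
        assert detect_death(s, death_anywhere=True) == 288

    def test_active_fly(self):
        assert detect_death(_series([1] * 576)) is None

    def test_exactly_24h_is_not_death(self):
        s = _series([3] * 288 + [0] * 288)
        assert detect_death(s) is None

    def test_censoring_truncates(self):
        s = _series([3] * 288 + [0] * (25 * 12))
        censored, death = censor_at_death(s)
        assert death == 288 and len(censored.counts) == 288


class TestSleep:
    def test_five_zero_minutes_is_sleep(self):
        ann = score_sleep(_series([0, 0, 0, 0, 0, 3], bin_minutes=1))
        assert ann.sleep.tolist() == [True] * 5 + [False]
        assert ann.bouts == [(0, 4)]

    def test_four_zero_minutes_is_not_sleep(self):
        ann = score_sleep(_series([0, 0, 0, 0, 3, 0], bin_minutes=1))
        assert not ann.sleep.any()
        assert ann.bouts == []

    def test_five_minute_bins_zero_is_sleep(self):
        # an all-zero day is exactly 24h immobility: sleep, not yet death
        ann = score_sleep(_series([0] * 288))
        assert ann.death_bin is None
        assert ann.sleep.sum() == 288 and ann.bouts == [(0, 287)]
        ann = score_sleep(_series([1] * 288 + [0] * 144 + [1] * 144))
        assert ann.sleep.sum() == 144
        assert ann.bouts == [(288, 431)]

    def test_sleep_plus_wake_partition_day(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(0.7, size=288)
        ann = score_sleep(_series(counts))
        assert ann.sleep.sum() + (~ann.sleep).sum() == 288


class TestBehaviorSummary:
    def test_constant_activity(self):
        s = _series([1] * 576)
        out = behavior_summary([s])
        assert (out["mean_activity"] == 1.0).all()
        assert (out["sleep_min"] == 0).all()

    def test_group_mean_sd(self):
        from tadakit.phenotype import group_mean_sd

        a = ActivitySeries("a", 5, np.full(288, 2))
        b = ActivitySeries("b", 5, np.full(288, 4))
        out = behavior_summary([a, b])
        mean, sd = group_mean_sd(out, "mean_activity")
        assert mean == 3.0 and sd == pytest.approx(np.sqrt(2))

    def test_photophase_scotophase_partition(self):
        counts = [0] * 144 + [2] * 144  # asleep all photophase, active at night
        out = behavior_summary([_series(counts)])
        row = out.iloc[0]
        assert row["sleep_min_photophase"] == 720
        assert row["sleep_min_scotophase"] == 0
        assert row["sleep_min"] == 720


class TestAnticipation:
    def test_uniform_activity_gives_half(self):
        s = _series([2] * 288 * 2)
        mean, ratios = anticipation_index(s, "lights_on")
        assert mean == pytest.approx(0.5)

    def test_all_activity_in_final_3h_gives_one(self):
        day = [0] * 216 + [5] * 72  # activity only in last 6h? last 72 bins = 6h
        day = [0] * 252 + [5] * 36  # last 36 bins = 3h
        s = _series(day * 2)
        mean, _ = anticipation_index(s, "lights_on")
        assert mean == pytest.approx(1.0)

    def test_linear_ramp(self):
        # ramp 0..71 over the 6h before lights-on: ratio = sum(36..71)/sum(0..71)
        day = [0] * 216 + list(range(72))
        s = _series(day)
        mean, _ = anticipation_index(s, "lights_on")
        expected = sum(range(36, 72)) / sum(range(72))
        assert mean == pytest.approx(expected)
        assert expected == pytest.approx(0.7535, abs=1e-3)

    def test_empty_window_day_excluded(self):
        s = _series([0] * 288 + [2] * 288)
        mean, ratios = anticipation_index(s, "lights_on")
        assert len(ratios) == 1  # first day's window is all zero

    def test_lights_off_transition(self):
        # activity only in the 3h before lights-off (ZT12)
        day = [0] * 108 + [4] * 36 + [0] * 144
        s = _series(day)
        mean, _ = anticipation_index(s, "lights_off")
        assert mean == pytest.approx(1.0)


class TestActogram:
    def test_shape(self):
        s = _series([1] * 576)
        assert actogram_matrix(s).shape == (2, 288)

    def test_resampling_sums(self):
        s = ActivitySeries("f", 1, np.array([1, 1, 1, 1, 1] * 288))
        r = resample_to_5min(s)
        assert (r.counts == 5).all()

    def test_double_plot(self):
        s = _series([1] * 288 * 3)
        assert actogram_matrix(s, double_plot=True).shape == (2, 576)

    def test_partial_day_dropped(self):
        s = _series([1] * (288 + 10))
        assert actogram_matrix(s).shape == (1, 288)


class TestPeriodogram:
    def test_constant_series_not_rhythmic(self):
        r = chi_square_periodogram(_series([5] * 288 * 4))
        assert (r.qp == 0).all()
        assert not r.rhythmic

    def test_noiseless_square_wave_exact_period(self):
        day = [10] * 144 + [0] * 144
        r = chi_square_periodogram(_series(day * 10))
        assert r.best_period_min == 1440.0
        assert r.rhythmic

    def test_resampling_consistency(self):
        rng = np.random.default_rng(1)
        counts1 = rng.poisson(2, size=1440 * 7)
        s1 = ActivitySeries("f", 1, counts1)
        s5 = resample_to_5min(s1)
        r1 = chi_square_periodogram(s5)
        r2 = chi_square_periodogram(resample_to_5min(s1))
        assert r1.best_period_min == r2.best_period_min
        np.testing.assert_allclose(r1.qp, r2.qp)

    def test_percent_rhythmic_and_long_period(self):
        base = chi_square_periodogram(
            _series(([10] * 144 + [0] * 144) * 7)
        )
        from dataclasses import replace

        r1 = replace(base, rhythmic=True, best_period_min=1440.0)
        r2 = replace(base, rhythmic=True, best_period_min=1445.0)
        r3 = replace(base, rhythmic=False)
        out = percent_rhythmic([r1, r2, r3, r1])
        assert out["fraction_rhythmic"] == 0.75
        assert out["table"]["long_period"].tolist() == [False, True, False, False]

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            percent_rhythmic([])


class TestCtcf:
    @pytest.mark.parametrize(
        "args,expected", [((100, 10, 2), 80.0), ((50, 10, 0), 50.0),
                          ((50, 100, 1), -50.0)]
    )
    def test_formula(self, args, expected):
        assert ctcf(*args) == expected

    def test_negative_area_rejected(self):
        with pytest.raises(ValueError):
            ctcf(10, -1, 1)
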