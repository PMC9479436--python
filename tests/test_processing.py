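"""Detector rules and day-composition accounting."""

import numpy as np
import pandas as pd
import pytest

from tucoda.processing import (
    classify_intensity,
    compute_day_composition,
    detect_nonwear,
    detect_sleep,
    filter_participants,
    process_stream,
    segment_days,
    sleep_mask_from_intervals,
)
from tucoda.simulate import DailyLog, make_daily_log, simulate_epoch_stream

COMP_COLS = ["sleep_min", "sed_min", "lpa_min", "mvpa_min"]


def _epochs(n, sd=(20.0, 20.0, 20.0), rg=(60.0, 60.0, 60.0), angle=0.0, enmo=10.0,
            start="2020-01-06 23:00"):
    ts = pd.date_range(start, periods=n, freq="5s")
    df = pd.DataFrame(
        {
            "timestamp": ts,
            "enmo_mg": enmo,
            "arm_angle_deg": angle,
            "sd_x_mg": sd[0],
            "sd_y_mg": sd[1],
            "sd_z_mg": sd[2],
            "range_x_mg": rg[0],
            "range_y_mg": rg[1],
            "range_z_mg": rg[2],
        }
    )
    return df


def _day_logs():
    log0 = make_daily_log("2020-01-06", "23:00", sleep_minutes=480.0)
    bed1 = log0.bedtime + pd.Timedelta(minutes=1440)
    log1 = DailyLog(date=log0.date + pd.Timedelta(days=1), bedtime=bed1,
                    waketime=bed1 + pd.Timedelta(minutes=1))
    return [log0, log1]


class TestNonwear:
    def test_constant_signal_all_nonwear(self):
        epochs = _epochs(2 * 60 * 12, sd=(0, 0, 0), rg=(0, 0, 0))
        assert not detect_nonwear(epochs).any()

    def test_two_axes_under_sd_threshold_is_nonwear(self):
        epochs = _epochs(15 * 12, sd=(5, 5, 40), rg=(200, 200, 200))
        assert not detect_nonwear(epochs).any()

    def test_active_windows_are_wear(self):
        epochs = _epochs(15 * 12, sd=(20, 20, 20), rg=(60, 60, 60))
        assert detect_nonwear(epochs).all()

    def test_single_low_axis_stays_wear(self):
        epochs = _epochs(15 * 12, sd=(5, 20, 20), rg=(40, 60, 60))
        assert detect_nonwear(epochs).all()

    def test_gap_in_timeline_is_an_error(self):
        epochs = _epochs(100)
        epochs.loc[60:, "timestamp"] += pd.Timedelta(seconds=35)
        with pytest.raises(ValueError, match="gap|irregular"):
            detect_nonwear(epochs)


class TestSleep:
    def test_constant_angle_fills_the_window(self):
        log = make_daily_log("2020-01-06", "23:00", sleep_minutes=480.0)
        epochs = _epochs(1440 * 12)
        intervals = detect_sleep(epochs, log)
        assert intervals == [(log.bedtime, log.waketime)]

    def test_restless_block_excluded_flanks_kept(self):
        log = make_daily_log("2020-01-06", "23:00", sleep_minutes=480.0)
        epochs = _epochs(1440 * 12)
        mid = 240 * 12  # oscillate 02:00-02:10
        osc = np.tile([20.0, -20.0], 60)
        epochs.loc[mid : mid + 119, "arm_angle_deg"] = osc
        intervals = detect_sleep(epochs, log)
        mask = sleep_mask_from_intervals(epochs, intervals)
        sleep_min = mask.sum() / 12.0
        assert sleep_min == pytest.approx(480.0 - 10.0, abs=1 / 6)
        assert not mask[mid : mid + 119].any()
        assert mask[: mid - 1].all()

    def test_calm_outside_the_logged_window_is_not_sleep(self):
        log = make_daily_log("2020-01-06", "23:00", sleep_minutes=60.0)
        # calm signal all day, but window is only one hour
        epochs = _epochs(1440 * 12)
        intervals = detect_sleep(epochs, log)
        mask = sleep_mask_from_intervals(epochs, intervals)
        assert mask.sum() / 12.0 == pytest.approx(60.0)

    def test_missing_log_yields_no_sleep_with_warning(self):
        epochs = _epochs(100)
        with pytest.warns(UserWarning, match="no daily log"):
            assert detect_sleep(epochs, None) == []

    def test_short_calm_span_not_counted(self):
        log = make_daily_log("2020-01-06", "23:00", sleep_minutes=30.0)
        epochs = _epochs(60 * 12)
        osc = np.tile([30.0, -30.0], 30 * 6)
        epochs["arm_angle_deg"] = np.concatenate([osc[: 26 * 12], np.zeros(4 * 12), osc[: 30 * 12]])
        intervals = detect_sleep(epochs, log)  # 4 calm minutes < 5-min floor
        assert intervals == []


class TestIntensity:
    @pytest.mark.parametrize(
        "enmo,label",
        [(0.0, "sed"), (29.999, "sed"), (30.0, "lpa"), (100.59, "lpa"), (100.6, "mvpa"), (250.0, "mvpa")],
    )
    def test_cutpoint_boundaries(self, enmo, label):
        assert classify_intensity([enmo])[0] == label

    def test_negative_enmo_rejected(self):
        with pytest.raises(ValueError):
            classify_intensity([-1.0])


class TestSegmentDays:
    def test_equal_bedtimes_give_24h_window(self):
        logs = _day_logs()
        (window,) = segment_days(logs)
        assert (window[1] - window[0]) == pd.Timedelta(hours=24)

    def test_earlier_second_bedtime_gives_23h(self):
        log0 = make_daily_log("2020-01-06", "23:00", sleep_minutes=480.0)
        bed1 = log0.bedtime + pd.Timedelta(hours=23)
        log1 = DailyLog(date=log0.date + pd.Timedelta(days=1), bedtime=bed1,
                        waketime=bed1 + pd.Timedelta(minutes=1))
        (window,) = segment_days([log0, log1])
        assert (window[1] - window[0]) == pd.Timedelta(hours=23)

    def test_seven_bedtimes_give_six_windows(self):
        logs = []
        for d in range(7):
            bed = pd.Timestamp("2020-01-06 23:00") + pd.Timedelta(days=d)
            logs.append(DailyLog(date=bed.normalize(), bedtime=bed,
                                 waketime=bed + pd.Timedelta(minutes=1)))
        assert len(segment_days(logs)) == 6

    def test_out_of_order_bedtimes_rejected(self):
        logs = _day_logs()[::-1]
        with pytest.raises(ValueError, match="out of order"):
            segment_days(logs)


class TestDayComposition:
    def test_round_trip_recovers_target_within_one_epoch(self):
        target = np.array([480.0, 660.0, 250.0, 50.0])
        log0, log1 = _day_logs()
        stream = simulate_epoch_stream(target, log0, seed=0)
        days = process_stream(stream, [log0, log1], "p", "pre")
        got = days.iloc[0][COMP_COLS].to_numpy(dtype=float)
        assert np.abs(got - target).max() <= 1 / 12 + 1e-9

    def test_partition_property(self):
        target = np.array([470.0, 640.0, 270.0, 60.0])
        log0, log1 = _day_logs()
        stream = simulate_epoch_stream(
            target, log0, seed=1, nonwear_blocks=[(780.0, 45.0)]
        )
        wear = detect_nonwear(stream)
        days = process_stream(stream, [log0, log1], "p", "pre")
        row = days.iloc[0]
        nonwear_min = (~wear).sum() / 12.0
        total = row[COMP_COLS].sum() + nonwear_min
        assert total == pytest.approx(row["day_length_min"], abs=1 / 12)

    def test_nonwear_never_increases_minutes(self):
        target = np.array([480.0, 660.0, 250.0, 50.0])
        log0, log1 = _day_logs()
        base = process_stream(
            simulate_epoch_stream(target, log0, seed=2), [log0, log1], "p", "pre"
        ).iloc[0]
        blocked = process_stream(
            simulate_epoch_stream(target, log0, seed=2, nonwear_blocks=[(600.0, 60.0)]),
            [log0, log1],
            "p",
            "pre",
        ).iloc[0]
        for col in COMP_COLS:
            assert blocked[col] <= base[col] + 1e-9

    def test_all_day_nonwear_is_empty_and_invalid(self):
        log0, log1 = _day_logs()
        stream = simulate_epoch_stream(
            [480.0, 660.0, 250.0, 50.0], log0, seed=3, nonwear_blocks=[(0.0, 1440.0)]
        )
        days = process_stream(stream, [log0, log1], "p", "pre")
        row = days.iloc[0]
        assert row[COMP_COLS].sum() == 0.0
        assert not row["valid"]

    @pytest.mark.parametrize("wear_min,expect_valid", [(599.0, False), (600.0, True)])
    def test_validity_fencepost(self, wear_min, expect_valid):
        # waking wear tuned to the minute through the sleep window
        sleep = 1440.0 - wear_min
        log0 = make_daily_log("2020-01-06", "23:00", sleep_minutes=sleep)
        log1 = _day_logs()[1]
        stream = simulate_epoch_stream(
            [sleep, 1440.0 - sleep, 0.0, 0.0], log0, seed=4
        )
        days = process_stream(stream, [log0, log1], "p", "pre")
        row = days.iloc[0]
        assert row["waking_wear_min"] == pytest.approx(wear_min)
        assert bool(row["valid"]) is expect_valid

    def test_empty_day_window_is_an_error(self):
        epochs = _epochs(100)
        window = (pd.Timestamp("2021-01-01"), pd.Timestamp("2021-01-02"))
        with pytest.raises(ValueError, match="no epochs"):
            compute_day_composition(epochs, window, np.ones(100, bool), [])


class TestParticipantFilter:
    @staticmethod
    def _days(pid, n_valid_pre, n_valid_post, n_days=7):
        rows = []
        for wave, n_valid in (("pre", n_valid_pre), ("post", n_valid_post)):
            for d in range(n_days):
                rows.append({"participant": pid, "wave": wave, "valid": d < n_valid})
        return rows

    def test_four_valid_days_in_both_waves_is_enough(self):
        df = pd.DataFrame(self._days("a", 4, 4))
        included, excluded = filter_participants(df)
        assert included == ["a"] and excluded.empty

    def test_three_valid_days_in_either_wave_excludes(self):
        df = pd.DataFrame(self._days("a", 7, 3) + self._days("b", 3, 7))
        included, excluded = filter_participants(df)
        assert included == []
        assert set(excluded["reason"]) == {"too_few_valid_days"}

    def test_missing_wave_excluded_with_reason(self):
        df = pd.DataFrame(
            [{"participant": "a", "wave": "pre", "valid": True} for _ in range(5)]
        )
        included, excluded = filter_participants(df)
        assert included == []
        assert excluded.iloc[0]["reason"] == "missing_wave"

    def test_empty_input_empty_output(self):
        df = pd.DataFrame(columns=["participant", "wave", "valid"])
        included, excluded = filter_participants(df)
        assert included == [] and excluded.empty
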