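"""Bout blocking: the nine window conditions, block search, day and week scores."""

import numpy as np
import pandas as pd
import pytest

from metbout.armband import (
    BlockingConfig,
    DayRecord,
    MetMinuteSeries,
    MonitorLog,
    MonitorLogEntry,
    find_blocks,
    impute_wear_time,
    is_valid_block,
    validate_day,
    weekly_score,
)

from conftest import DAY_START, full_day, minute_frame

CFG = BlockingConfig()


def seq(*chunks):
    """Concatenate (met_value, n_minutes) chunks into a MET array."""
    return np.concatenate([np.full(n, float(v)) for v, n in chunks])


class TestIsValidBlock:
    @pytest.mark.parametrize(
        "met, valid, reason",
        [
            # clean 12-minute bout: every condition holds
            (seq((4.0, 12)), True, None),
            # below the 10-minute floor
            (seq((6.0, 9)), False, "duration_below_minimum"),
            # 8/10 active with one 2-minute interior rest: exactly at the
            # 80 % short-block bound and the 2-minute rest cap
            (seq((4.0, 4), (2.0, 2), (4.0, 4)), True, None),
            # 7/10 active fails the 80 % requirement first
            (seq((4.0, 4), (2.0, 3), (4.0, 3)), False, "active_fraction_too_low"),
            # 40-minute block: one 4-minute rest allowed, 36/40 = 90 % active
            (seq((4.0, 18), (2.0, 4), (4.0, 18)), True, None),
            # endpoints must be at or above threshold
            (seq((2.0, 1), (4.0, 11)), False, "endpoint_not_active"),
            (seq((4.0, 11), (3.2, 1)), False, "endpoint_not_active"),
            # 3-minute rest: barred in a 15-minute block, fine in a 16-minute one
            (seq((4.0, 6), (2.0, 3), (4.0, 6)), False, "rest_run_too_long"),
            (seq((4.0, 7), (2.0, 3), (4.0, 6)), True, None),
            # 4-minute rest: barred below 30 minutes, allowed at exactly 30
            (seq((4.0, 13), (2.0, 4), (4.0, 12)), False, "rest_run_too_long"),
            (seq((4.0, 13), (2.0, 4), (4.0, 13)), True, None),
            # two 4-minute rests: barred at exactly 60 minutes, allowed above
            (seq((4.0, 18), (2.0, 4), (4.0, 18), (2.0, 4), (4.0, 16)), False, "rest_run_too_long"),
            (seq((4.0, 18), (2.0, 4), (4.0, 18), (2.0, 4), (4.0, 17)), True, None),
            # a 5-minute rest never passes, whatever the duration
            (seq((4.0, 40), (2.0, 5), (4.0, 40)), False, "rest_run_too_long"),
            # threshold boundary: MET exactly 3.3 is active
            (seq((3.3, 10)), True, None),
        ],
    )
    def test_window_conditions(self, met, valid, reason):
        ok, why = is_valid_block(met, CFG)
        assert ok is valid
        assert why == reason

    def test_too_short_window_rejected(self):
        with pytest.raises(ValueError):
            is_valid_block([4.0], CFG)


class TestFindBlocks:
    def test_sedentary_day_has_no_blocks(self):
        assert find_blocks(full_day(), CFG) == []

    def test_single_clean_bout(self):
        day = full_day([(i, 5.0) for i in range(480, 505)])
        blocks = find_blocks(day, CFG, "P001")
        assert len(blocks) == 1
        b = blocks[0]
        assert b.duration_minutes == 25
        assert b.met_minutes == pytest.approx(125.0)
        assert b.n_rest_minutes == 0
        assert b.start == DAY_START + pd.Timedelta(minutes=480)
        assert b.end == DAY_START + pd.Timedelta(minutes=504)

    def test_sub_ten_minute_bouts_are_dropped(self):
        day = full_day([(i, 5.0) for i in range(480, 489)])
        assert find_blocks(day, CFG) == []

    def test_padding_invariance(self):
        met = seq((4.0, 15), (2.0, 2), (5.0, 20))
        bare = find_blocks(minute_frame(met, DAY_START + pd.Timedelta(minutes=300)), CFG)
        padded = find_blocks(
            minute_frame(
                np.concatenate([np.full(300, 1.2), met, np.full(200, 1.2)]), DAY_START
            ),
            CFG,
        )
        assert [(b.start, b.end, b.met_minutes) for b in bare] == [
            (b.start, b.end, b.met_minutes) for b in padded
        ]

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            met = rng.uniform(0.9, 8.0, size=150)
            day = minute_frame(met)
            totals = []
            for thr in (3.0, 3.3, 3.8, 4.5):
                cfg = BlockingConfig(met_threshold=thr)
                totals.append(sum(b.met_minutes for b in find_blocks(day, cfg)))
            assert all(a >= b for a, b in zip(totals, totals[1:]))

    def test_blocks_do_not_cross_offbody_minutes(self):
        met = seq((5.0, 30))
        frame = minute_frame(met)
        frame.loc[10:14, "on_body"] = False  # device removed mid-bout
        blocks = find_blocks(frame, CFG)
        assert all(b.duration_minutes >= 10 for b in blocks)
        covered = set()
        for b in blocks:
            t = b.start
            while t <= b.end:
                covered.add(int((t - DAY_START).total_seconds() // 60))
                t += pd.Timedelta(minutes=1)
        assert covered.isdisjoint(range(10, 15))


class TestValidateDay:
    def test_full_day_is_valid(self):
        rec = validate_day(full_day(), "P1", CFG)
        assert rec.is_valid and rec.on_body_minutes == 1440
        assert not rec.is_weekend  # a Monday

    @pytest.mark.parametrize("on_minutes, valid", [(1295, False), (1296, True)])
    def test_wear_time_boundary(self, on_minutes, valid):
        day = full_day()
        day.loc[on_minutes:, "on_body"] = False
        rec = validate_day(day, "P1", CFG)
        assert rec.on_body_minutes == on_minutes
        assert rec.is_valid is valid

    def test_blocked_score_never_exceeds_minutewise(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            met = rng.uniform(0.9, 8.0, size=1440)
            rec = validate_day(minute_frame(met), "P1", CFG)
            assert rec.daily_score_blocked <= rec.daily_score_minutewise + 1e-9

    def test_weekend_flag(self):
        sat = full_day(start=pd.Timestamp("2012-06-09 00:00"))
        assert validate_day(sat, "P1", CFG).is_weekend


class TestImputeWearTime:
    def _series(self, off=()):
        frame = full_day()
        for a, b in off:
            frame.loc[a : b - 1, "on_body"] = False
        return MetMinuteSeries("P1", frame)

    def test_empty_log_is_identity(self):
        s = self._series(off=[(600, 660)])
        out = impute_wear_time(s, MonitorLog("P1", []))
        pd.testing.assert_frame_equal(out.minutes, s.minutes)

    def test_logged_gap_becomes_wear_time_with_intensity_met(self):
        s = self._series(off=[(600, 660)])
        entry = MonitorLogEntry(
            DAY_START + pd.Timedelta(minutes=600),
            DAY_START + pd.Timedelta(minutes=660),
            "swimming",
            "moderate",
        )
        out = impute_wear_time(s, MonitorLog("P1", [entry]))
        window = out.minutes.iloc[600:660]
        assert window["on_body"].all() and window["imputed"].all()
        assert (window["met"] == 4.0).all()
        # wear time never decreases
        assert out.minutes["on_body"].sum() >= s.minutes["on_body"].sum()

    def test_logged_minutes_push_day_over_validity(self):
        s = self._series(off=[(600, 790)])  # 1250 native on-body minutes
        entry = MonitorLogEntry(
            DAY_START + pd.Timedelta(minutes=600),
            DAY_START + pd.Timedelta(minutes=650),
            "shower",
            "low",
        )
        out = impute_wear_time(s, MonitorLog("P1", [entry]))
        rec = validate_day(out.minutes, "P1", CFG)
        assert rec.on_body_minutes == 1300
        assert rec.is_valid

    def test_imputed_minutes_excluded_from_blocks_by_default(self):
        s = self._series(off=[(600, 660)])
        entry = MonitorLogEntry(
            DAY_START + pd.Timedelta(minutes=600),
            DAY_START + pd.Timedelta(minutes=660),
            "netball",
            "vigorous",
        )
        out = impute_wear_time(s, MonitorLog("P1", [entry]))
        assert find_blocks(out.minutes, CFG) == []
        opt_in = BlockingConfig(include_imputed_in_blocks=True)
        assert len(find_blocks(out.minutes, opt_in)) == 1

    def test_overlapping_entries_rejected(self):
        t = DAY_START + pd.Timedelta(minutes=600)
        with pytest.raises(ValueError):
            MonitorLog(
                "P1",
                [
                    MonitorLogEntry(t, t + pd.Timedelta(minutes=30), "a", "low"),
                    MonitorLogEntry(t + pd.Timedelta(minutes=10), t + pd.Timedelta(minutes=40), "b", "low"),
                ],
            )

    def test_entry_outside_series_range_rejected(self):
        s = self._series()
        entry = MonitorLogEntry(
            DAY_START + pd.Timedelta(days=30),
            DAY_START + pd.Timedelta(days=30, minutes=10),
            "x",
            "low",
        )
        with pytest.raises(ValueError):
            impute_wear_time(s, MonitorLog("P1", [entry]))


def day_record(date, weekend, score, valid=True):
    return DayRecord("P1", date, weekend, 1440 if valid else 100, valid, score, score)


class TestWeeklyScore:
    def test_five_two_formula(self):
        days = [day_record(pd.Timestamp("2012-06-04").date() + pd.Timedelta(days=i).to_pytimedelta(), i >= 5, 100.0 if i < 5 else 50.0) for i in range(7)]
        wk = weekly_score(days)
        assert wk.included
        assert wk.avg_weekday_score == pytest.approx(100.0)
        assert wk.avg_weekend_score == pytest.approx(50.0)
        assert wk.weekly_total == pytest.approx(600.0)

    def test_three_valid_days_excluded(self):
        base = pd.Timestamp("2012-06-04").date()
        days = [
            day_record(base + pd.Timedelta(days=i).to_pytimedelta(), i >= 5, 100.0, valid=i < 3)
            for i in range(7)
        ]
        wk = weekly_score(days)
        assert not wk.included and wk.weekly_total is None

    def test_minimum_inclusion_arithmetic(self):
        base = pd.Timestamp("2012-06-04").date()
        days = [
            day_record(base, False, 80.0),
            day_record(base + pd.Timedelta(days=1).to_pytimedelta(), False, 120.0),
            day_record(base + pd.Timedelta(days=5).to_pytimedelta(), True, 60.0),
            day_record(base + pd.Timedelta(days=6).to_pytimedelta(), True, 60.0),
        ]
        wk = weekly_score(days)
        assert wk.included
        assert wk.weekly_total == pytest.approx(5 * 100.0 + 2 * 60.0)

    def test_weekend_days_required(self):
        base = pd.Timestamp("2012-06-04").date()
        days = [
            day_record(base + pd.Timedelta(days=i).to_pytimedelta(), i >= 5, 100.0, valid=i != 6)
            for i in range(7)
        ]  # only one valid weekend day
        assert not weekly_score(days).included

    def test_formula_identity_is_exact(self):
        rng = np.random.default_rng(5)
        base = pd.Timestamp("2012-06-04").date()
        for _ in range(50):
            days = [
                day_record(
                    base + pd.Timedelta(days=i).to_pytimedelta(),
                    i >= 5,
                    float(rng.uniform(0, 500)),
                    valid=bool(rng.random() < 0.9),
                )
                for i in range(7)
            ]
            wk = weekly_score(days)
            if wk.included:
                assert wk.weekly_total == 5.0 * wk.avg_weekday_score + 2.0 * wk.avg_weekend_score

    def test_duplicate_dates_rejected(self):
        d = day_record(pd.Timestamp("2012-06-04").date(), False, 1.0)
        with pytest.raises(ValueError):
            weekly_score([d, d])
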