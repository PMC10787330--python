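"""Geofence state machine, haversine distance and day classification."""

from datetime import timedelta

import numpy as np
import pytest

from workmode.gps_labeling import (PipelineConfig, WorkInterval, classify_day,
                                   DayRecord, haversine_km, label_work_intervals,
                                   minute_gps_state)
from workmode.grid import EVAL_START_MIN, N_EVAL_MINUTES
from tests.conftest import TZ, make_gps, ts

CFG = PipelineConfig()
WORK = (25.0, 121.5)
FAR = (25.5, 122.0)  # ~75 km away


def track(spec):
    """spec: list of (hour_float, at_work: bool); fixes at 600-s cadence."""
    pts = []
    for h, at in spec:
        t = ts(1, 0) + timedelta(hours=h)
        pts.append((t, *(WORK if at else FAR)))
    return make_gps(pts)


def cadence_track(start_h, end_h, in_lo, in_hi):
    pts = []
    t = ts(1, int(start_h))
    while t <= ts(1, 0) + timedelta(hours=end_h):
        h = (t - ts(1, 0)).total_seconds() / 3600.0
        pts.append((h, in_lo <= h < in_hi))
        t += timedelta(seconds=600)
    return track(pts)


class TestHaversine:
    def test_identical_points_are_zero(self):
        assert haversine_km(25.0, 121.5, 25.0, 121.5) == 0.0

    def test_one_degree_longitude_at_equator(self):
        # closed form: R * pi / 180 with R = 6371 km
        assert haversine_km(0, 0, 0, 1) == pytest.approx(111.19, abs=0.01)

    def test_symmetry_over_random_pairs(self):
        rng = np.random.default_rng(0)
        a = rng.uniform([-90, -180], [90, 180], size=(50, 2))
        b = rng.uniform([-90, -180], [90, 180], size=(50, 2))
        d1 = haversine_km(a[:, 0], a[:, 1], b[:, 0], b[:, 1])
        d2 = haversine_km(b[:, 0], b[:, 1], a[:, 0], a[:, 1])
        assert np.allclose(d1, d2)
        assert (d1 >= 0).all()

    def test_latitude_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            haversine_km(91, 0, 0, 0)


def oracle_intervals(times, in_range, confirm_s=1800.0):
    """Independent run-scan of the dwell rule (backdated start, last-in end).

    Scans every fix; opens an interval at the first fix of an in-range run
    that persists >= confirm_s with no interruption, closes it at the last
    in-range fix once > confirm_s pass with no in-range detection.
    """
    out = []
    open_start = None
    last_in = None
    run_start = None
    prev_in_t = None
    for t, inr in zip(times, in_range):
        if open_start is None:
            if inr:
                if run_start is None or (t - prev_in_t).total_seconds() > confirm_s:
                    run_start = t
                prev_in_t = t
                if (t - run_start).total_seconds() >= confirm_s:
                    open_start, last_in = run_start, t
                    run_start = prev_in_t = None
            else:
                run_start = prev_in_t = None
        else:
            if inr and (t - last_in).total_seconds() <= confirm_s:
                last_in = t
            elif (t - last_in).total_seconds() > confirm_s:
                out.append((open_start, last_in))
                open_start = None
                if inr:
                    run_start = prev_in_t = t
    if open_start is not None:
        out.append((open_start, last_in))
    return out


class TestWorkIntervals:
    def test_always_far_yields_no_intervals(self):
        assert label_work_intervals(cadence_track(6, 22, 99, 99), [WORK], CFG) == []

    def test_single_block_recovered_with_backdating(self):
        ivs = label_work_intervals(cadence_track(6, 22, 9, 17), [WORK], CFG)
        assert len(ivs) == 1
        assert ivs[0].start == ts(1, 9)
        # last in-range fix before 17:00
        assert ivs[0].end == ts(1, 16, 50)

    def test_short_excursion_does_not_split(self):
        pts = []
        t = ts(1, 6)
        while t <= ts(1, 22):
            h = (t - ts(1, 0)).total_seconds() / 3600.0
            at = 9 <= h < 17 and not (12.0 <= h < 12.3)  # 20-min excursion
            pts.append((h, at))
            t += timedelta(seconds=600)
        ivs = label_work_intervals(track(pts), [WORK], CFG)
        assert len(ivs) == 1

    def test_empty_workplace_list_rejected(self):
        with pytest.raises(ValueError):
            label_work_intervals(cadence_track(6, 22, 9, 17), [], CFG)

    def test_matches_run_scan_oracle_on_random_tracks(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(10, 120))
            t = ts(1, 0) + timedelta(minutes=int(rng.integers(0, 120)))
            times, flags = [], []
            for _ in range(n):
                times.append(t)
                # occasional gaps beyond the confirmation period
                step = 600 if rng.random() > 0.05 else int(rng.integers(1800, 5400))
                t = t + timedelta(seconds=step)
            state = 0
            for _ in range(n):
                if rng.random() < 0.15:
                    state = 1 - state
                flags.append(bool(state))
            gps = make_gps([(tt, *(WORK if f else FAR)) for tt, f in zip(times, flags)])
            got = [(iv.start, iv.end) for iv in label_work_intervals(gps, [WORK], CFG)]
            exp = []
            for s, e in oracle_intervals(times, flags):
                # implementation additionally splits at midnight
                cur = s
                while cur.date() < e.date():
                    nxt = (cur + timedelta(days=1)).replace(hour=0, minute=0,
                                                            second=0, microsecond=0)
                    exp.append((cur, nxt))
                    cur = nxt
                if cur < e:
                    exp.append((cur, e))
            assert got == exp

    def test_second_workplace_counts_as_in_range(self):
        gps = cadence_track(6, 22, 9, 17)
        ivs = label_work_intervals(gps, [(24.0, 120.0), WORK], CFG)
        assert len(ivs) == 1


class TestMinuteState:
    def test_no_intervals_all_zero(self):
        assert minute_gps_state([], ts(1, 0).date()).sum() == 0

    def test_eight_hour_block_has_480_minutes(self):
        iv = WorkInterval(ts(1, 9), ts(1, 17))
        s = minute_gps_state([iv], ts(1, 0).date())
        assert int(s.sum()) == 480

    def test_rasterization_equals_membership_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            ivs = []
            cur = int(rng.integers(0, 600))
            while cur < 1380:
                length = int(rng.integers(1, 240))
                ivs.append(WorkInterval(ts(1, 0) + timedelta(minutes=cur),
                                        ts(1, 0) + timedelta(minutes=min(cur + length, 1440))))
                cur += length + int(rng.integers(1, 180))
            s = minute_gps_state(ivs, ts(1, 0).date())
            for m in range(N_EVAL_MINUTES):
                lo = ts(1, 0) + timedelta(minutes=EVAL_START_MIN + m)
                hi = lo + timedelta(minutes=1)
                member = any(iv.start < hi and iv.end > lo for iv in ivs)
                assert bool(s[m]) == member

    def test_sum_equals_clipped_interval_minutes(self):
        ivs = [WorkInterval(ts(1, 3), ts(1, 7)),  # partially before 05:45
               WorkInterval(ts(1, 9), ts(1, 12))]
        s = minute_gps_state(ivs, ts(1, 0).date())
        assert int(s.sum()) == (7 * 60 - EVAL_START_MIN) + 180


class TestClassifyDay:
    def _day(self, ivs):
        rec = DayRecord(date=ts(1, 0).date(), work_intervals=ivs)
        rec.minute_state = minute_gps_state(ivs, rec.date)
        return rec

    def test_no_intervals_is_holiday(self):
        assert classify_day(self._day([]), CFG) == "holiday"

    def test_standard_day_is_typical(self):
        day = self._day([WorkInterval(ts(1, 9), ts(1, 17))])
        assert classify_day(day, CFG) == "typical"

    def test_afternoon_start_is_other(self):
        day = self._day([WorkInterval(ts(1, 13), ts(1, 19))])
        assert classify_day(day, CFG) == "other"

    def test_short_day_is_other(self):
        day = self._day([WorkInterval(ts(1, 9), ts(1, 12))])
        assert classify_day(day, CFG) == "other"

    def test_working_at_midnight_is_other(self):
        day = self._day([WorkInterval(ts(1, 9), ts(2, 0) - timedelta(seconds=1))])
        assert classify_day(day, CFG) == "other"
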