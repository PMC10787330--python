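"""GPS-defined work hours: geofence state machine and day classification.

Work-hour recording follows a dwell rule: recording begins when the device
is detected within ``geofence_radius_km`` (default 1 km) of any registered
workplace for a continuous ``confirm_s`` (default 1800 s) period, and ceases
after a continuous ``confirm_s`` period without such a detection.  Fixes
arrive at a nominal 600-s cadence; gaps longer than ``confirm_s`` count as
absence of detection.

Boundary convention: the 1800-s confirmation is treated as detection
latency, so a work interval starts at the *first* fix of the qualifying
in-range run and ends at the *last* in-range fix before the qualifying
out-of-range run.  Without backdating, every episode would be shaved by
~30 minutes at each end.

Day classes:

``typical``
    off-working at both ends of the evaluated span (05:45 and 23:59), first
    work interval starting before noon, and total work duration (sum of
    intervals) above four hours.  Only these days train the classifier.
``holiday``
    no GPS fix ever within range of a worksite (zero work hours).
``other``
    everything else (night shifts, short days, on-call patterns).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, time, timedelta

import numpy as np
import pandas as pd

from .grid import EVAL_START_MIN, EVAL_END_MIN, N_EVAL_MINUTES

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class PipelineConfig:
    """Numeric constants of the whole pipeline, in one place."""

    geofence_radius_km: float = 1.0
    confirm_s: float = 1800.0
    gps_cadence_s: float = 600.0
    window_s: float = 1800.0
    night_end_min: int = EVAL_START_MIN  # data in [00:00, 05:45) excluded
    prob_threshold: float = 0.5
    transition_exclusion_min: int = 15
    auc_floor: float = 0.7
    greedy_delta: float = 0.01
    min_typical_days: int = 5

    def __post_init__(self):
        for name in ("geofence_radius_km", "confirm_s", "gps_cadence_s",
                     "window_s", "night_end_min", "transition_exclusion_min",
                     "auc_floor", "greedy_delta", "min_typical_days"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.prob_threshold < 1.0:
            raise ValueError("prob_threshold must be in (0, 1)")


@dataclass(frozen=True)
class WorkInterval:
    """One GPS-defined work span, within a single calendar day."""

    start: datetime
    end: datetime

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("WorkInterval start must precede end")

    @property
    def duration_s(self) -> float:
        return (self.end - self.start).total_seconds()


@dataclass
class DayRecord:
    """GPS-derived description of one participant-day."""

    date: object  # datetime.date
    work_intervals: list = field(default_factory=list)
    day_class: str = "other"
    minute_state: np.ndarray | None = None  # binary, 05:45-24:00 grid


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray | float:
    """Great-circle distance in km (spherical Earth, R = 6371 km).

    Accepts scalars or arrays; symmetric, non-negative, zero iff the points
    coincide.
    """
    lat1, lon1, lat2, lon2 = (np.asarray(x, dtype=float) for x in (lat1, lon1, lat2, lon2))
    for lat in (lat1, lat2):
        if np.any(np.abs(lat) > 90.0):
            raise ValueError("latitude outside [-90, 90]")
    for lon in (lon1, lon2):
        if np.any(np.abs(lon) > 180.0):
            raise ValueError("longitude outside [-180, 180]")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlmb = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlmb / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return d if d.shape else float(d)


def _split_at_midnight(start: datetime, end: datetime) -> list[WorkInterval]:
    out = []
    cur = start
    while cur.date() < end.date():
        nxt = datetime.combine(cur.date() + timedelta(days=1), time(0, 0),
                               tzinfo=cur.tzinfo)
        if cur < nxt:
            out.append(WorkInterval(cur, nxt))
        cur = nxt
    if cur < end:
        out.append(WorkInterval(cur, end))
    return out


def label_work_intervals(track: pd.DataFrame, workplaces, cfg: PipelineConfig) -> list[WorkInterval]:
    """Run the dwell state machine over one participant's GPS track.

    ``track`` must be time-sorted with ``timestamp``, ``lat``, ``lon``
    columns; ``workplaces`` is a non-empty sequence of (lat, lon) pairs (a
    fix is in range if within the geofence radius of *any* of them).
    Returns disjoint, sorted intervals split at local midnight.
    """
    if len(workplaces) == 0:
        raise ValueError("at least one workplace is required")
    if track.empty:
        return []
    times = list(track["timestamp"])
    lat = track["lat"].to_numpy(dtype=float)
    lon = track["lon"].to_numpy(dtype=float)
    in_range = np.zeros(len(track), dtype=bool)
    for wlat, wlon in workplaces:
        in_range |= haversine_km(lat, lon, wlat, wlon) <= cfg.geofence_radius_km

    raw: list[tuple[datetime, datetime]] = []
    state = "out"
    run_start = None     # first fix of current candidate in-range run
    run_prev = None      # previous in-range fix of the candidate run
    interval_start = None
    last_in = None       # last in-range fix while recording

    for t, inr in zip(times, in_range):
        if state == "out":
            if inr:
                if run_start is None or (t - run_prev).total_seconds() > cfg.confirm_s:
                    run_start = t
                run_prev = t
                if (t - run_start).total_seconds() >= cfg.confirm_s:
                    state, interval_start, last_in = "in", run_start, t
                    run_start = run_prev = None
            else:
                run_start = run_prev = None
        else:  # recording
            if inr and (t - last_in).total_seconds() <= cfg.confirm_s:
                last_in = t
            elif (t - last_in).total_seconds() > cfg.confirm_s:
                raw.append((interval_start, last_in))
                state, interval_start = "out", None
                if inr:  # this fix opens a fresh candidate run
                    run_start = run_prev = t
                else:
                    run_start = run_prev = None
            # else: short out-of-range excursion, keep waiting
    if state == "in":
        raw.append((interval_start, last_in))

    out: list[WorkInterval] = []
    for s, e in raw:
        if e > s:
            out.extend(_split_at_midnight(s, e))
    return out


def minute_gps_state(intervals: list[WorkInterval], date) -> np.ndarray:
    """Rasterize a day's work intervals onto the 05:45-24:00 minute grid.

    Minute m is 1 iff the half-open minute [m, m+1) intersects any interval.
    """
    state = np.zeros(N_EVAL_MINUTES, dtype=np.int8)
    if not intervals:
        return state
    tz = intervals[0].start.tzinfo
    day0 = datetime.combine(date, time(0, 0), tzinfo=tz)
    for iv in intervals:
        if iv.start.date() != date:
            continue
        s = (iv.start - day0).total_seconds() / 60.0
        e = (iv.end - day0).total_seconds() / 60.0
        lo = max(int(np.floor(s)), EVAL_START_MIN)
        hi = min(int(np.ceil(e)), EVAL_END_MIN)
        if hi > lo:
            state[lo - EVAL_START_MIN:hi - EVAL_START_MIN] = 1
    return state


def classify_day(day: DayRecord, cfg: PipelineConfig) -> str:
    """Assign typical / holiday / other from intervals and minute state."""
    if not day.work_intervals:
        return "holiday"
    if day.minute_state is None:
        raise ValueError("minute_state must be computed before classification")
    ms = day.minute_state
    off_at_ends = ms[0] == 0 and ms[-1] == 0
    first_start = min(iv.start for iv in day.work_intervals)
    before_noon = first_start.hour < 12
    total_h = sum(iv.duration_s for iv in day.work_intervals) / 3600.0
    if off_at_ends and before_noon and total_h > 4.0:
        return "typical"
    return "other"


def label_days(gps: pd.DataFrame, workplaces, cfg: PipelineConfig) -> dict:
    """Full per-day labeling for one participant's GPS track.

    Returns {date: DayRecord} covering every date with at least one fix.
    """
    intervals = label_work_intervals(gps, workplaces, cfg)
    by_date: dict = {}
    for iv in intervals:
        by_date.setdefault(iv.start.date(), []).append(iv)
    days = {}
    for date in sorted({t.date() for t in gps["timestamp"]}):
        ivs = sorted(by_date.get(date, []), key=lambda iv: iv.start)
        rec = DayRecord(date=date, work_intervals=ivs)
        rec.minute_state = minute_gps_state(ivs, date)
        rec.day_class = classify_day(rec, cfg)
        days[date] = rec
    return days


def workhours_frame(participant_id: str, days: dict) -> pd.DataFrame:
    """Flatten day records into the workhours.csv layout."""
    rows = []
    for date, rec in sorted(days.items()):
        if rec.work_intervals:
            for iv in rec.work_intervals:
                rows.append((participant_id, str(date), iv.start.isoformat(),
                             iv.end.isoformat(), rec.day_class))
        else:
            rows.append((participant_id, str(date), "", "", rec.day_class))
    return pd.DataFrame(rows, columns=["participant_id", "date", "start", "end", "day_class"])
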