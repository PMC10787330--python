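"""On-disk formats for event logs, GPS logs and derived artifacts.

Everything is plain CSV with ISO-8601 timestamps carrying explicit UTC
offsets.  Column dictionaries:

``events.csv``
    participant_id, timestamp, kind (screen_on | screen_off | notification),
    app_label (active app for screen_on, source app for notification, may be
    empty for screen_off).

``gps.csv``
    participant_id, timestamp, lat, lon (WGS84 degrees, ~600 s cadence).

``truth.csv``
    participant_id, date, minute (0..1439), state
    (office | break_at_work | off | remote).

``workhours.csv``
    participant_id, date, start, end, day_class (typical | holiday | other).
    Holidays appear with empty start/end.

``prob.csv``
    participant_id, timestamp, provisional, final — one row per evaluated
    minute (05:45-24:00).

``segmentation.csv``
    participant_id, date, minute (minute-of-day), state.

``summary.csv``
    participant_id, date, office_h, break_h, off_h, remote_h,
    prob_work_h, gps_work_h.

``features.csv``
    participant_id, window_start, label, then 5 columns per app
    (<app>_f1 .. <app>_f5); missing values are empty cells.

Writers accept an optional ``meta`` mapping emitted as ``# key=value``
comment lines before the header; readers skip ``#`` lines.  Internal
computation happens in the participant's local time zone (default UTC+8),
because all the wall-clock rules (night exclusion, "before noon") are local.
"""

from __future__ import annotations

import io
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .grid import DEFAULT_TZ

EVENT_KINDS = ("screen_on", "screen_off", "notification")

EVENT_COLUMNS = ["participant_id", "timestamp", "kind", "app_label"]
GPS_COLUMNS = ["participant_id", "timestamp", "lat", "lon"]
TRUTH_COLUMNS = ["participant_id", "date", "minute", "state"]
PROB_COLUMNS = ["participant_id", "timestamp", "provisional", "final"]
SEGMENTATION_COLUMNS = ["participant_id", "date", "minute", "state"]
SUMMARY_COLUMNS = [
    "participant_id", "date", "office_h", "break_h", "off_h", "remote_h",
    "prob_work_h", "gps_work_h",
]
WORKHOURS_COLUMNS = ["participant_id", "date", "start", "end", "day_class"]


class ParseError(ValueError):
    """Malformed row in an input file; carries the 1-based line number."""

    def __init__(self, path, line: int, message: str):
        self.path = path
        self.line = line
        super().__init__(f"{path}:{line}: {message}")


def _count_comment_lines(path) -> int:
    n = 0
    with open(path, "r", encoding="utf-8") as fh:
        for raw in fh:
            if raw.startswith("#"):
                n += 1
            else:
                break
    return n


def _read_csv(path, required: list[str]) -> tuple[pd.DataFrame, int]:
    """Read a CSV, skipping # comments; return (frame, header line offset)."""
    offset = _count_comment_lines(path)
    df = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(path, offset + 1, f"missing columns {missing}")
    return df, offset


def _parse_timestamps(df, path, offset, column="timestamp", tz=DEFAULT_TZ):
    ts = pd.to_datetime(df[column], errors="coerce", utc=True, format="ISO8601")
    bad = ts.isna().to_numpy()
    if bad.any():
        idx = int(np.flatnonzero(bad)[0])
        raise ParseError(path, idx + offset + 2,
                         f"malformed timestamp {df[column].iloc[idx]!r}")
    return ts.dt.tz_convert(tz)


def _write_csv(df: pd.DataFrame, path, meta: Mapping | None = None) -> None:
    buf = io.StringIO()
    if meta:
        for k, v in meta.items():
            buf.write(f"# {k}={v}\n")
    df.to_csv(buf, index=False)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


# ---------------------------------------------------------------- events


def read_events(path, tz=DEFAULT_TZ) -> pd.DataFrame:
    """Load an event log, validating kinds and timestamps.

    Returns records sorted by (participant_id, timestamp); the record count
    is preserved.  Unknown kinds or malformed timestamps raise
    :class:`ParseError` naming the offending line.
    """
    df, offset = _read_csv(path, EVENT_COLUMNS)
    kinds = df["kind"].to_numpy()
    bad = ~np.isin(kinds, EVENT_KINDS)
    if bad.any():
        idx = int(np.flatnonzero(bad)[0])
        raise ParseError(path, idx + offset + 2, f"unknown event kind {kinds[idx]!r}")
    df = df.assign(timestamp=_parse_timestamps(df, path, offset, tz=tz))
    df = df.sort_values(["participant_id", "timestamp"], kind="stable")
    return df[EVENT_COLUMNS].reset_index(drop=True)


def write_events(path, events: pd.DataFrame, meta: Mapping | None = None) -> None:
    out = events[EVENT_COLUMNS].copy()
    out["timestamp"] = out["timestamp"].map(lambda t: t.isoformat())
    _write_csv(out, path, meta)


# ------------------------------------------------------------------- gps


def read_gps(path, tz=DEFAULT_TZ) -> pd.DataFrame:
    """Load a GPS track; coordinates are range-checked."""
    df, offset = _read_csv(path, GPS_COLUMNS)
    for col, lo, hi in (("lat", -90.0, 90.0), ("lon", -180.0, 180.0)):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals < lo) | (vals > hi)
        if bad.any():
            idx = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(path, idx + offset + 2,
                             f"{col}={df[col].iloc[idx]!r} outside [{lo}, {hi}]")
        df[col] = vals
    df = df.assign(timestamp=_parse_timestamps(df, path, offset, tz=tz))
    df = df.sort_values(["participant_id", "timestamp"], kind="stable")
    return df[GPS_COLUMNS].reset_index(drop=True)


def write_gps(path, gps: pd.DataFrame, meta: Mapping | None = None) -> None:
    out = gps[GPS_COLUMNS].copy()
    out["timestamp"] = out["timestamp"].map(lambda t: t.isoformat())
    _write_csv(out, path, meta)


# ----------------------------------------------------------- ground truth


def read_ground_truth(path) -> pd.DataFrame:
    df, _ = _read_csv(path, TRUTH_COLUMNS)
    df["minute"] = df["minute"].astype(int)
    return df[TRUTH_COLUMNS]


def write_ground_truth(path, truth: pd.DataFrame, meta: Mapping | None = None) -> None:
    _write_csv(truth[TRUTH_COLUMNS], path, meta)


# ------------------------------------------------------ probability series


def write_probability_series(path, series: pd.DataFrame,
                             meta: Mapping | None = None) -> None:
    """Write a per-minute probability series (prob.csv).

    Minutes must be contiguous (60-s steps) within each participant-day.
    """
    if len(series):
        for (_, _), grp in series.groupby(
                [series["participant_id"],
                 series["timestamp"].map(lambda t: t.date())], sort=False):
            steps = grp["timestamp"].diff().dropna().dt.total_seconds()
            if len(steps) and not (steps == 60).all():
                raise ValueError("probability series minutes are not contiguous")
    out = series[PROB_COLUMNS].copy()
    out["timestamp"] = out["timestamp"].map(lambda t: t.isoformat())
    _write_csv(out, path, meta)


def read_probability_series(path, tz=DEFAULT_TZ) -> pd.DataFrame:
    df, offset = _read_csv(path, PROB_COLUMNS)
    df = df.assign(timestamp=_parse_timestamps(df, path, offset, tz=tz))
    for col in ("provisional", "final"):
        df[col] = pd.to_numeric(df[col])
    return df[PROB_COLUMNS]


# ------------------------------------------------------------ segmentation


def write_segmentation(path, seg: pd.DataFrame, meta: Mapping | None = None) -> None:
    _write_csv(seg[SEGMENTATION_COLUMNS], path, meta)


def read_segmentation(path) -> pd.DataFrame:
    df, _ = _read_csv(path, SEGMENTATION_COLUMNS)
    df["minute"] = df["minute"].astype(int)
    return df[SEGMENTATION_COLUMNS]


def write_summary(path, summary: pd.DataFrame, meta: Mapping | None = None) -> None:
    _write_csv(summary[SUMMARY_COLUMNS], path, meta)


def write_workhours(path, rows: pd.DataFrame, meta: Mapping | None = None) -> None:
    _write_csv(rows[WORKHOURS_COLUMNS], path, meta)


def read_workhours(path, tz=DEFAULT_TZ) -> pd.DataFrame:
    df, _ = _read_csv(path, WORKHOURS_COLUMNS)
    for col in ("start", "end"):
        parsed = pd.to_datetime(df[col].replace("", pd.NaT), utc=True,
                                format="ISO8601", errors="raise")
        df[col] = parsed.dt.tz_convert(tz)
    return df[WORKHOURS_COLUMNS]


# ---------------------------------------------------------------- features


def write_features(path, X: pd.DataFrame, labels: Iterable, meta_cols: pd.DataFrame,
                   meta: Mapping | None = None) -> None:
    """features.csv: participant_id, window_start, label, <app>_f1..f5."""
    out = meta_cols.copy()
    out["label"] = list(labels)
    out = pd.concat([out.reset_index(drop=True), X.reset_index(drop=True)], axis=1)
    out["window_start"] = out["window_start"].map(lambda t: t.isoformat())
    _write_csv(out, path, meta)


def read_features(path, tz=DEFAULT_TZ) -> pd.DataFrame:
    df, offset = _read_csv(path, ["participant_id", "window_start", "label"])
    df = df.replace("", np.nan)
    df["window_start"] = _parse_timestamps(df, path, offset, column="window_start", tz=tz)
    df["label"] = df["label"].astype(int)
    feat_cols = [c for c in df.columns if c not in ("participant_id", "window_start", "label")]
    for c in feat_cols:
        df[c] = pd.to_numeric(df[c])
    return df
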