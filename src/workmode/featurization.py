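"""Screen-event featurization: 5 features per app per 1800-s window.

For every app in the participant's vocabulary a window carries:

f1  usage_duration_s        seconds of that app's usage episodes, clipped
                            to the window
f2  notif_in_episode_count  notifications of that app arriving inside one
                            of its own usage episodes
f3  notif_outside_count     notifications of that app arriving outside its
                            episodes
f4  reaction_time_s         mean delay from a notification to the start of
                            the usage episode it triggered (episodes
                            starting in the window)
f5  reaction_intensity_s    mean duration of those notification-triggered
                            episodes

f4/f5 are missing (NaN) when no notification-triggered episode starts in
the window; f1-f3 are zero for vocabulary apps absent from the window.
The feature vector length is 5 x |vocabulary|.

Stimulus-response pairing: a usage episode reacts to the most recent
notification of the same app that arrived at or before the episode start
and after the previous episode of that app.  This mirrors reaction-time
measurement in mental chronometry: the response is attributed to the
nearest preceding stimulus, and a notification already answered by an
earlier episode is not reused.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import datetime, time, timedelta

import numpy as np
import pandas as pd

from .grid import EVAL_START_MIN, EVAL_END_MIN, N_EVAL_MINUTES
from .gps_labeling import PipelineConfig

FEATURE_SUFFIXES = ("f1", "f2", "f3", "f4", "f5")


@dataclass(frozen=True)
class UsageEpisode:
    """One screen_on -> screen_off span attributed to a single app."""

    app_label: str
    start: datetime
    end: datetime
    clipped: bool = False  # closed artificially at end of day

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("episode start must precede end")


def feature_names(vocab) -> list[str]:
    return [f"{app}_{sfx}" for app in vocab for sfx in FEATURE_SUFFIXES]


def extract_episodes(events: pd.DataFrame) -> list[UsageEpisode]:
    """Pair screen_on/screen_off events into usage episodes.

    Events must be time-sorted.  A screen_on while another episode is open
    closes the previous episode at the new screen_on (zero-gap app switch);
    a trailing unmatched screen_on is closed at local midnight and flagged;
    a screen_off with no open episode is dropped with a warning.
    """
    episodes: list[UsageEpisode] = []
    open_app = None
    open_t = None
    for row in events.itertuples(index=False):
        if row.kind == "screen_on":
            if open_app is not None and row.timestamp > open_t:
                episodes.append(UsageEpisode(open_app, open_t, row.timestamp))
            open_app, open_t = row.app_label, row.timestamp
        elif row.kind == "screen_off":
            if open_app is None:
                warnings.warn("screen_off without matching screen_on; dropped")
                continue
            if row.timestamp > open_t:
                episodes.append(UsageEpisode(open_app, open_t, row.timestamp))
            open_app = open_t = None
    if open_app is not None:
        day_end = datetime.combine(open_t.date() + timedelta(days=1), time(0, 0),
                                   tzinfo=open_t.tzinfo)
        if day_end > open_t:
            episodes.append(UsageEpisode(open_app, open_t, day_end, clipped=True))
    return episodes


def pair_notifications(episodes: list[UsageEpisode],
                       notifications: pd.DataFrame) -> pd.DataFrame:
    """Attribute episodes to triggering notifications (see module docstring).

    Returns one row per notification-triggered episode with columns
    app_label, notif_time, ep_start, reaction_s, intensity_s.
    """
    rows = []
    if len(notifications):
        notif_by_app = {app: grp["timestamp"].to_list()
                        for app, grp in notifications.groupby("app_label")}
    else:
        notif_by_app = {}
    prev_start_by_app: dict[str, datetime] = {}
    for ep in sorted(episodes, key=lambda e: e.start):
        cand = notif_by_app.get(ep.app_label)
        if cand:
            lo = prev_start_by_app.get(ep.app_label)
            best = None
            for t in cand:  # sorted; streams are small per day
                if t > ep.start:
                    break
                if lo is None or t > lo:
                    best = t
            if best is not None:
                rows.append((ep.app_label, best, ep.start,
                             (ep.start - best).total_seconds(),
                             (ep.end - ep.start).total_seconds()))
        # notifications inside or before this episode are consumed
        prev_start_by_app[ep.app_label] = ep.end
    return pd.DataFrame(rows, columns=["app_label", "notif_time", "ep_start",
                                       "reaction_s", "intensity_s"])


def _notif_in_episode_flags(notifications: pd.DataFrame,
                            episodes: list[UsageEpisode]) -> np.ndarray:
    """True where a notification falls inside a same-app episode [start, end)."""
    flags = np.zeros(len(notifications), dtype=bool)
    eps_by_app: dict[str, list[UsageEpisode]] = {}
    for ep in episodes:
        eps_by_app.setdefault(ep.app_label, []).append(ep)
    for i, row in enumerate(notifications.itertuples(index=False)):
        for ep in eps_by_app.get(row.app_label, ()):
            if ep.start <= row.timestamp < ep.end:
                flags[i] = True
                break
    return flags


class WindowFeaturizer:
    """Precomputes episodes/pairs once, then evaluates arbitrary windows.

    The per-minute path (:meth:`minute_matrix`) and the per-window path
    (:meth:`window_vector`) implement the same definitions; windows ending
    on minute boundaries agree exactly between the two.
    """

    def __init__(self, events: pd.DataFrame, vocab, cfg: PipelineConfig | None = None):
        self.cfg = cfg or PipelineConfig()
        self.vocab = list(vocab)
        self.events = events
        self.episodes = extract_episodes(events)
        self.notifications = events[events["kind"] == "notification"].reset_index(drop=True)
        self.notif_inside = _notif_in_episode_flags(self.notifications, self.episodes)
        self.pairs = pair_notifications(self.episodes, self.notifications)

    # ------------------------------------------------------------ window

    def window_vector(self, window_start: datetime,
                      window_s: float | None = None) -> np.ndarray:
        """Feature vector (5 x |vocab|) for the window [start, start+1800 s)."""
        ws = window_start
        span = self.cfg.window_s if window_s is None else window_s
        if span != self.cfg.window_s:
            raise ValueError(f"window must be {self.cfg.window_s} s long")
        we = ws + timedelta(seconds=span)
        out = np.zeros(5 * len(self.vocab))
        for j, app in enumerate(self.vocab):
            base = 5 * j
            usage = 0.0
            for ep in self.episodes:
                if ep.app_label != app:
                    continue
                lo, hi = max(ep.start, ws), min(ep.end, we)
                if hi > lo:
                    usage += (hi - lo).total_seconds()
            out[base] = usage
            n_in = n_out = 0
            for t, inside, a in zip(self.notifications["timestamp"],
                                    self.notif_inside,
                                    self.notifications["app_label"]):
                if a == app and ws <= t < we:
                    if inside:
                        n_in += 1
                    else:
                        n_out += 1
            out[base + 1], out[base + 2] = n_in, n_out
            if len(self.pairs):
                sel = ((self.pairs["app_label"] == app)
                       & (self.pairs["ep_start"] >= ws)
                       & (self.pairs["ep_start"] < we))
                if sel.any():
                    out[base + 3] = float(self.pairs.loc[sel, "reaction_s"].mean())
                    out[base + 4] = float(self.pairs.loc[sel, "intensity_s"].mean())
                else:
                    out[base + 3] = out[base + 4] = np.nan
            else:
                out[base + 3] = out[base + 4] = np.nan
        return out

    # ------------------------------------------------------- minute grid

    def minute_matrix(self, date) -> np.ndarray:
        """Features for the 1095 trailing windows ending at each evaluated
        minute of ``date`` (window ending at minute t covers [t-30 min, t)).

        Computed with per-minute bins and rolling sums; exactly equivalent
        to :meth:`window_vector` because those windows are minute-aligned.
        """
        V = len(self.vocab)
        app_idx = {a: j for j, a in enumerate(self.vocab)}
        w = int(self.cfg.window_s // 60)
        tz = None
        usage = np.zeros((V, 1440))
        n_in = np.zeros((V, 1440))
        n_out = np.zeros((V, 1440))
        p_cnt = np.zeros((V, 1440))
        p_rt = np.zeros((V, 1440))
        p_int = np.zeros((V, 1440))

        for ep in self.episodes:
            j = app_idx.get(ep.app_label)
            if j is None:
                continue
            tz = tz or ep.start.tzinfo
            day0 = datetime.combine(date, time(0, 0), tzinfo=ep.start.tzinfo)
            day1 = day0 + timedelta(days=1)
            lo, hi = max(ep.start, day0), min(ep.end, day1)
            if hi <= lo:
                continue
            s = (lo - day0).total_seconds()
            e = (hi - day0).total_seconds()
            b0, b1 = int(s // 60), int(np.ceil(e / 60.0)) - 1
            if b0 == b1:
                usage[j, b0] += e - s
            else:
                usage[j, b0] += (b0 + 1) * 60 - s
                usage[j, b0 + 1:b1] += 60.0
                usage[j, b1] += e - b1 * 60

        for row, inside in zip(self.notifications.itertuples(index=False),
                               self.notif_inside):
            j = app_idx.get(row.app_label)
            if j is None or row.timestamp.date() != date:
                continue
            m = row.timestamp.hour * 60 + row.timestamp.minute
            (n_in if inside else n_out)[j, m] += 1

        for row in self.pairs.itertuples(index=False):
            j = app_idx.get(row.app_label)
            if j is None or row.ep_start.date() != date:
                continue
            m = row.ep_start.hour * 60 + row.ep_start.minute
            p_cnt[j, m] += 1
            p_rt[j, m] += row.reaction_s
            p_int[j, m] += row.intensity_s

        def trailing(x):
            # sum over bins [t-w, t) for each evaluated end-minute t
            c = np.concatenate([np.zeros((V, 1)), np.cumsum(x, axis=1)], axis=1)
            t = np.arange(EVAL_START_MIN, EVAL_END_MIN)
            return c[:, t] - c[:, t - w]

        U, NI, NO = trailing(usage), trailing(n_in), trailing(n_out)
        PC, PR, PI = trailing(p_cnt), trailing(p_rt), trailing(p_int)
        with np.errstate(invalid="ignore", divide="ignore"):
            F4 = np.where(PC > 0, PR / np.maximum(PC, 1), np.nan)
            F5 = np.where(PC > 0, PI / np.maximum(PC, 1), np.nan)
        X = np.empty((N_EVAL_MINUTES, 5 * V))
        for j in range(V):
            X[:, 5 * j + 0] = U[j]
            X[:, 5 * j + 1] = NI[j]
            X[:, 5 * j + 2] = NO[j]
            X[:, 5 * j + 3] = F4[j]
            X[:, 5 * j + 4] = F5[j]
        return X


def compute_window_features(events: pd.DataFrame, window_start: datetime,
                            vocab, cfg: PipelineConfig | None = None,
                            window_s: float | None = None) -> np.ndarray:
    """One-shot convenience wrapper around :class:`WindowFeaturizer`."""
    return WindowFeaturizer(events, vocab, cfg).window_vector(window_start, window_s)


def infer_vocabulary(events: pd.DataFrame) -> list[str]:
    """App labels observed in screen_on or notification events, sorted."""
    sel = events["kind"].isin(["screen_on", "notification"])
    labels = sorted(set(events.loc[sel, "app_label"]) - {""})
    return labels


def build_training_set(day_records: dict, events: pd.DataFrame,
                       cfg: PipelineConfig, vocab=None):
    """Labeled 1800-s training windows from typical workdays.

    Windows are aligned to local midnight at an 1800-s stride.  Dropped:
    windows intersecting the night span [00:00, 05:45), windows containing
    both on- and off-working minutes (mixed GPS label), and whole days with
    no screen events.  Labels come from the GPS minute state (1 = at work).

    Returns ``(X, y, meta)`` with X a DataFrame (NaN = missing), y an int
    array and meta a DataFrame (participant-day date, window_start).
    """
    if vocab is None:
        typ_dates = {d for d, r in day_records.items() if r.day_class == "typical"}
        vocab = infer_vocabulary(
            events[events["timestamp"].map(lambda t: t.date()).isin(typ_dates)])
    stride = int(cfg.window_s // 60)
    rows, labels, meta = [], [], []
    events_by_date = dict(tuple(events.groupby(events["timestamp"].map(lambda t: t.date()))))
    for date, rec in sorted(day_records.items()):
        if rec.day_class != "typical":
            continue
        day_events = events_by_date.get(date)
        if day_events is None or not (day_events["kind"] != "notification").any():
            continue  # no screen events recorded that day
        fz = WindowFeaturizer(day_events, vocab, cfg)
        tz = day_events["timestamp"].iloc[0].tzinfo
        day0 = datetime.combine(date, time(0, 0), tzinfo=tz)
        first = int(np.ceil(cfg.night_end_min / stride)) * stride
        for w0 in range(first, EVAL_END_MIN - stride + 1, stride):
            win = rec.minute_state[w0 - EVAL_START_MIN:w0 + stride - EVAL_START_MIN]
            if win.min() != win.max():
                continue  # mixed on/off window
            rows.append(fz.window_vector(day0 + timedelta(minutes=w0)))
            labels.append(int(win[0]))
            meta.append((date, w0))
    if not rows:
        raise ValueError("no training windows survive the exclusion rules")
    X = pd.DataFrame(np.vstack(rows), columns=feature_names(vocab))
    y = np.asarray(labels, dtype=int)
    meta_df = pd.DataFrame(meta, columns=["date", "window_start_min"])
    return X, y, meta_df, vocab


class SamplingImputer:
    """Missing-value imputation by sampling with replacement from the
    observed values of each column (fit on training folds only)."""

    def __init__(self):
        self.observed_: dict[str, np.ndarray] | None = None

    def fit(self, X: pd.DataFrame) -> "SamplingImputer":
        obs = {}
        for c in X.columns:
            vals = X[c].to_numpy(dtype=float)
            vals = vals[~np.isnan(vals)]
            if vals.size == 0:
                raise ValueError(f"column {c!r} has no observed values")
            obs[c] = vals
        self.observed_ = obs
        return self

    def transform(self, X: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
        if self.observed_ is None:
            raise RuntimeError("imputer is not fitted")
        out = X.copy()
        for c in X.columns:
            col = out[c].to_numpy(dtype=float)
            miss = np.isnan(col)
            if miss.any():
                col[miss] = rng.choice(self.observed_[c], size=int(miss.sum()),
                                       replace=True)
                out[c] = col
        return out


def impute_missing(X: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Impute in one shot: fit on X itself, then fill (training-time use)."""
    return SamplingImputer().fit(X).transform(X, rng)
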