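"""Synthetic participants: event streams + GPS tracks with known truth.

The generator emulates what the logging app measures: Poisson notification
arrivals per app, probabilistic responses with log-normally distributed
reaction times, log-normal usage-episode durations, self-initiated usage
episodes, a daily schedule (commute, office blocks, breaks at the worksite,
evening remote-work episodes, holidays) and a 600-s GPS track with
isotropic Gaussian location noise.

Two behavioral regimes exist: *work* (minutes spent office-working or
remote-working) and *off* (breaks at the worksite and genuine off time).
Breaks keep the body at the worksite while interaction behavior switches to
the off regime; remote work is the mirror case — exactly the signal the
classifier must detect.  The ``contrast`` knob in [0, 1] interpolates each
app's off-regime parameters toward its work-regime parameters (1 = fully
separated regimes, 0 = indistinguishable).

Daily-schedule magnitudes default to the observed cohort-level aggregates
of hospital staff (about 10.2 h of GPS-defined work, ~55 min of breaks and
~110 min of evening remote work per workday, holidays at 2/7); per-app
rates, response probabilities, reaction-time and episode-duration medians
are free choices documented in docs/methods.md.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace
from datetime import date as date_cls, datetime, time, timedelta, timezone

import numpy as np
import pandas as pd

from .grid import SECONDS_PER_DAY

STATE_OFF, STATE_OFFICE, STATE_BREAK, STATE_REMOTE = "off", "office", "break_at_work", "remote"
STATES = (STATE_OFFICE, STATE_BREAK, STATE_OFF, STATE_REMOTE)

#: events are only generated from this minute on (sleep before 06:00)
WAKE_MIN = 6 * 60

MAX_WORKPLACES = 5


@dataclass(frozen=True)
class AppBehavior:
    """Per-app interaction parameters, one value per regime (work / off).

    Rates are events/hour; reaction times and episode durations are
    log-normal with the given median (s) and log-scale dispersion.
    """

    name: str
    notif_rate: tuple[float, float]        # (work, off) notifications/h
    response_prob: tuple[float, float]
    reaction_median_s: tuple[float, float]
    reaction_sigma: tuple[float, float]
    episode_median_s: tuple[float, float]
    episode_sigma: tuple[float, float]
    self_rate: tuple[float, float]         # self-initiated episodes/h

    def __post_init__(self):
        for r in (*self.notif_rate, *self.self_rate):
            if r < 0:
                raise ValueError("rates must be non-negative")
        for p in self.response_prob:
            if not 0.0 <= p <= 1.0:
                raise ValueError("response probabilities must be in [0, 1]")


# Full-contrast behavior table: work-oriented apps are answered fast and
# briefly at work; leisure apps are answered fast and at length off work.
BASE_APPS = (
    AppBehavior("Phone", (5.0, 1.0), (0.9, 0.5), (5.0, 60.0), (0.6, 0.8),
                (90.0, 180.0), (0.7, 0.7), (1.5, 0.5)),
    AppBehavior("Email", (7.0, 1.0), (0.85, 0.3), (8.0, 300.0), (0.6, 0.9),
                (120.0, 90.0), (0.7, 0.7), (3.0, 0.3)),
    AppBehavior("Slack", (9.0, 1.5), (0.9, 0.4), (6.0, 240.0), (0.6, 0.9),
                (60.0, 60.0), (0.7, 0.7), (3.0, 0.5)),
    AppBehavior("YouTube", (0.7, 2.5), (0.1, 0.8), (600.0, 15.0), (0.9, 0.6),
                (120.0, 900.0), (0.7, 0.8), (0.2, 1.5)),
    AppBehavior("Instagram", (1.0, 4.0), (0.15, 0.85), (400.0, 10.0), (0.9, 0.6),
                (60.0, 420.0), (0.7, 0.8), (0.3, 2.5)),
    AppBehavior("Messenger", (1.5, 4.0), (0.3, 0.9), (200.0, 8.0), (0.8, 0.6),
                (60.0, 300.0), (0.7, 0.8), (0.5, 2.0)),
)


@dataclass(frozen=True)
class SimConfig:
    """Cohort-level simulation settings."""

    contrast: float = 1.0
    n_workplaces: int = 1
    start_date: date_cls = date_cls(2021, 3, 1)
    tz_offset_hours: float = 8.0
    gps_cadence_s: float = 600.0
    gps_noise_sd_km: float = 0.05
    commute_min: float = 30.0
    holiday_prob: float = 2.0 / 7.0
    work_start_mean_min: float = 8 * 60 + 30
    work_start_sd_min: float = 40.0
    work_dur_mean_h: float = 10.2
    work_dur_sd_h: float = 1.2
    lunch_start_mean_min: float = 12 * 60 + 15
    lunch_dur_mean_min: float = 40.0
    coffee_breaks_per_day: float = 1.0
    coffee_dur_mean_min: float = 15.0
    remote_episodes_per_evening: float = 1.5
    remote_dur_mean_min: float = 75.0
    rate_jitter_sd: float = 0.15

    def __post_init__(self):
        if not 0.0 <= self.contrast <= 1.0:
            raise ValueError("contrast must be in [0, 1]")
        if not 1 <= self.n_workplaces <= MAX_WORKPLACES:
            raise ValueError(f"n_workplaces must be in [1, {MAX_WORKPLACES}]")
        if not 0.0 <= self.holiday_prob <= 1.0:
            raise ValueError("holiday_prob must be in [0, 1]")


@dataclass(frozen=True)
class ParticipantProfile:
    """Everything needed to simulate one participant."""

    participant_id: str
    home: tuple[float, float]
    workplaces: tuple[tuple[float, float], ...]
    apps: tuple[AppBehavior, ...]
    config: SimConfig

    def __post_init__(self):
        if not 1 <= len(self.workplaces) <= MAX_WORKPLACES:
            raise ValueError(f"a profile may have 1..{MAX_WORKPLACES} workplaces")


def _geo_blend(on: float, off: float, c: float) -> tuple[float, float]:
    """Shrink a (work, off) pair of positive scales toward their geometric
    mean as contrast decreases (c = 1 keeps full separation)."""
    if on <= 0 or off <= 0:
        mid = 0.5 * (on + off)
        return on * c + mid * (1 - c), off * c + mid * (1 - c)
    mid = float(np.sqrt(on * off))
    return (on ** c * mid ** (1 - c), off ** c * mid ** (1 - c))


def _lin_blend(on: float, off: float, c: float) -> tuple[float, float]:
    mid = 0.5 * (on + off)
    return on * c + mid * (1 - c), off * c + mid * (1 - c)


def generate_participant(seed: int, config: SimConfig | None = None) -> ParticipantProfile:
    """Deterministically derive one participant profile from a seed.

    Locations are scattered around a reference city center; app parameters
    are the base table at the configured contrast level with mild per-person
    log-normal jitter on the rates.
    """
    config = config or SimConfig()
    rng = np.random.default_rng([int(seed), 0x5ea5])
    pid = f"sim{int(seed):04d}"
    center = (25.03, 121.52)
    home = (center[0] + rng.uniform(-0.05, 0.05), center[1] + rng.uniform(-0.05, 0.05))
    workplaces = []
    for _ in range(config.n_workplaces):
        bearing = rng.uniform(0, 2 * np.pi)
        dist_km = rng.uniform(6.0, 12.0)
        workplaces.append((home[0] + dist_km * np.cos(bearing) / 110.574,
                           home[1] + dist_km * np.sin(bearing)
                           / (111.320 * np.cos(np.radians(home[0])))))
    c = config.contrast
    apps = []
    for base in BASE_APPS:
        jit = float(rng.lognormal(0.0, config.rate_jitter_sd))
        nr = _geo_blend(*base.notif_rate, c)
        sr = _geo_blend(*base.self_rate, c)
        apps.append(replace(
            base,
            notif_rate=(nr[0] * jit, nr[1] * jit),
            self_rate=(sr[0] * jit, sr[1] * jit),
            response_prob=_lin_blend(*base.response_prob, c),
            reaction_median_s=_geo_blend(*base.reaction_median_s, c),
            episode_median_s=_geo_blend(*base.episode_median_s, c),
        ))
    return ParticipantProfile(pid, home, tuple(workplaces), tuple(apps), config)


# -------------------------------------------------------------- schedule


def simulate_schedule(profile: ParticipantProfile, n_days: int,
                      rng: np.random.Generator):
    """Per-day minute-state arrays (1440 entries) plus day flags.

    Returns a list of (date, states: np.array of state strings, is_holiday).
    Invariants: office/break minutes imply presence at the worksite; remote
    minutes are off-site; holidays contain no office/break minutes.
    """
    cfg = profile.config
    days = []
    for d in range(n_days):
        date = cfg.start_date + timedelta(days=d)
        states = np.array([STATE_OFF] * 1440, dtype=object)
        holiday = bool(rng.random() < cfg.holiday_prob)
        work_span = None
        if not holiday:
            start = -1.0
            while not 0 <= start < 720:  # must start before noon
                start = rng.normal(cfg.work_start_mean_min, cfg.work_start_sd_min)
            dur = max(4.5, rng.normal(cfg.work_dur_mean_h, cfg.work_dur_sd_h)) * 60
            start = int(round(start))
            end = int(min(start + round(dur), 23 * 60))
            states[start:end] = STATE_OFFICE
            work_span = (start, end)
            # breaks: one lunch plus Poisson coffee breaks, all inside work
            breaks = []
            l0 = int(round(rng.normal(cfg.lunch_start_mean_min, 20)))
            ld = max(10, int(round(rng.normal(cfg.lunch_dur_mean_min, 10))))
            breaks.append((l0, l0 + ld))
            for _ in range(rng.poisson(cfg.coffee_breaks_per_day)):
                b0 = int(rng.uniform(start + 60, end - 60))
                bd = max(5, int(round(rng.normal(cfg.coffee_dur_mean_min, 5))))
                breaks.append((b0, b0 + bd))
            occupied = []
            for b0, b1 in sorted(breaks):
                b0, b1 = max(b0, start + 30), min(b1, end - 30)
                if b1 <= b0 or any(b0 < o1 + 10 and b1 > o0 - 10 for o0, o1 in occupied):
                    continue
                states[b0:b1] = STATE_BREAK
                occupied.append((b0, b1))
        # evening remote-work episodes (work or holiday evenings alike)
        evening_start = (work_span[1] + int(cfg.commute_min) + 20) if work_span else 18 * 60
        for _ in range(rng.poisson(cfg.remote_episodes_per_evening)):
            rd = max(15, int(round(rng.normal(cfg.remote_dur_mean_min, 20))))
            hi = 23 * 60 + 45 - rd
            if hi <= evening_start:
                continue
            r0 = int(rng.uniform(evening_start, hi))
            seg = states[r0:r0 + rd]
            if np.all(seg == STATE_OFF):
                states[r0:r0 + rd] = STATE_REMOTE
        days.append((date, states, holiday))
    return days


# ---------------------------------------------------------------- events


def _regime_of_states(states: np.ndarray) -> np.ndarray:
    """0 = off-regime behavior, 1 = work-regime behavior, -1 = asleep."""
    regime = np.where(np.isin(states, [STATE_OFFICE, STATE_REMOTE]), 1, 0)
    regime[:WAKE_MIN] = -1
    return regime


def simulate_days(profile: ParticipantProfile, n_days: int, seed: int):
    """Simulate event + GPS streams and ground truth for one participant.

    Returns ``(events, gps, truth)`` DataFrames in the ingest_io layouts.
    Deterministic given (seed, participant_id): the RNG stream is derived
    from both, so cohorts are reproducible participant by participant.
    """
    if n_days < 0:
        raise ValueError("n_days must be >= 0")
    cfg = profile.config
    tz = timezone(timedelta(hours=cfg.tz_offset_hours))
    rng = np.random.default_rng([int(seed), zlib.crc32(profile.participant_id.encode())])
    schedule = simulate_schedule(profile, n_days, rng)

    ev_rows, gps_rows, truth_rows = [], [], []
    for date, states, holiday in schedule:
        day0 = datetime.combine(date, time(0, 0), tzinfo=tz)
        regime = _regime_of_states(states)
        day_end_s = SECONDS_PER_DAY - 1

        # --- notifications + response episodes + self-initiated episodes
        notifs = []       # (t_s, app)
        candidates = []   # (start_s, dur_s, app)
        for app in profile.apps:
            for reg in (0, 1):
                mins = np.flatnonzero(regime == reg)
                if mins.size == 0:
                    continue
                counts = rng.poisson(app.notif_rate[1 - reg] / 60.0, size=mins.size)
                for m, k in zip(mins[counts > 0], counts[counts > 0]):
                    for _ in range(int(k)):
                        t = m * 60 + int(rng.integers(0, 60))
                        notifs.append((t, app.name))
                        if rng.random() < app.response_prob[1 - reg]:
                            rt = rng.lognormal(np.log(app.reaction_median_s[1 - reg]),
                                               app.reaction_sigma[1 - reg])
                            dur = rng.lognormal(np.log(app.episode_median_s[1 - reg]),
                                                app.episode_sigma[1 - reg])
                            candidates.append((t + max(1, int(round(rt))),
                                               max(5.0, dur), app.name))
                scount = rng.poisson(app.self_rate[1 - reg] / 60.0, size=mins.size)
                for m, k in zip(mins[scount > 0], scount[scount > 0]):
                    for _ in range(int(k)):
                        t = m * 60 + int(rng.integers(0, 60))
                        dur = rng.lognormal(np.log(app.episode_median_s[1 - reg]),
                                            app.episode_sigma[1 - reg])
                        candidates.append((t, max(5.0, dur), app.name))

        # single screen: keep the earliest episode of any overlapping pair
        candidates.sort()
        cursor = -1
        for start_s, dur, app_name in candidates:
            if start_s <= cursor or start_s >= day_end_s:
                continue
            end_s = min(int(start_s + round(dur)), day_end_s)
            if end_s <= start_s:
                continue
            ev_rows.append((profile.participant_id, day0 + timedelta(seconds=int(start_s)),
                            "screen_on", app_name))
            ev_rows.append((profile.participant_id, day0 + timedelta(seconds=end_s),
                            "screen_off", ""))
            cursor = end_s
        for t, app_name in notifs:
            ev_rows.append((profile.participant_id, day0 + timedelta(seconds=int(t)),
                            "notification", app_name))

        # --- GPS track
        work = profile.workplaces[0]
        at_site = np.isin(states, [STATE_OFFICE, STATE_BREAK])
        site_mins = np.flatnonzero(at_site)
        span = (int(site_mins[0]), int(site_mins[-1]) + 1) if site_mins.size else None
        for t_s in range(0, SECONDS_PER_DAY, int(cfg.gps_cadence_s)):
            m = t_s / 60.0
            lat, lon = profile.home
            if span is not None:
                s0, s1 = span
                c0, c1 = s0 - cfg.commute_min, s1 + cfg.commute_min
                if s0 <= m < s1:
                    lat, lon = work
                elif c0 <= m < s0:
                    f = (m - c0) / cfg.commute_min
                    lat = profile.home[0] + f * (work[0] - profile.home[0])
                    lon = profile.home[1] + f * (work[1] - profile.home[1])
                elif s1 <= m < c1:
                    f = (m - s1) / cfg.commute_min
                    lat = work[0] + f * (profile.home[0] - work[0])
                    lon = work[1] + f * (profile.home[1] - work[1])
            if cfg.gps_noise_sd_km > 0:
                lat = lat + rng.normal(0, cfg.gps_noise_sd_km) / 110.574
                lon = lon + rng.normal(0, cfg.gps_noise_sd_km) / (
                    111.320 * np.cos(np.radians(lat)))
            gps_rows.append((profile.participant_id,
                             day0 + timedelta(seconds=t_s), lat, lon))

        for m in range(1440):
            truth_rows.append((profile.participant_id, str(date), m, states[m]))

    events = pd.DataFrame(ev_rows, columns=["participant_id", "timestamp", "kind", "app_label"])
    if len(events):
        events = events.sort_values(["participant_id", "timestamp"],
                                    kind="stable").reset_index(drop=True)
    gps = pd.DataFrame(gps_rows, columns=["participant_id", "timestamp", "lat", "lon"])
    truth = pd.DataFrame(truth_rows, columns=["participant_id", "date", "minute", "state"])
    return events, gps, truth


def simulate_cohort(n_participants: int, n_days: int, seed: int,
                    config: SimConfig | None = None):
    """Simulate a cohort; participant i uses profile seed ``seed + i``.

    Returns (events, gps, truth, profiles) with frames concatenated across
    participants.
    """
    config = config or SimConfig()
    ev, gp, tr, profiles = [], [], [], []
    for i in range(n_participants):
        profile = generate_participant(seed + i, config)
        e, g, t = simulate_days(profile, n_days, seed)
        ev.append(e)
        gp.append(g)
        tr.append(t)
        profiles.append(profile)
    cat = lambda xs: pd.concat(xs, ignore_index=True) if xs else pd.DataFrame()
    return cat(ev), cat(gp), cat(tr), profiles
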