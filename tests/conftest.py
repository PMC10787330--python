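"""Shared fixtures: tiny synthetic participants and event builders."""

from __future__ import annotations

from datetime import datetime, timedelta, timezone

import numpy as np
import pandas as pd
import pytest

from workmode import SimConfig, generate_participant, simulate_days

TZ = timezone(timedelta(hours=8))


def ts(day: int, h: int, m: int = 0, s: int = 0) -> datetime:
    """Timestamp on 2021-03-<day> local time."""
    return datetime(2021, 3, day, h, m, s, tzinfo=TZ)


def make_events(rows) -> pd.DataFrame:
    """rows: (timestamp, kind, app_label) for a single participant."""
    return pd.DataFrame(
        [("p1", t, k, a) for t, k, a in rows],
        columns=["participant_id", "timestamp", "kind", "app_label"],
    )


def make_gps(points) -> pd.DataFrame:
    """points: (timestamp, lat, lon) for a single participant."""
    return pd.DataFrame(
        [("p1", t, la, lo) for t, la, lo in points],
        columns=["participant_id", "timestamp", "lat", "lon"],
    )


@pytest.fixture(scope="session")
def profile():
    return generate_participant(1)


@pytest.fixture(scope="session")
def small_sim(profile):
    """10 simulated days for one participant (events, gps, truth)."""
    return simulate_days(profile, 10, seed=1)


@pytest.fixture(scope="session")
def noiseless_profile():
    cfg = SimConfig(gps_noise_sd_km=0.0, holiday_prob=0.0)
    return generate_participant(2, cfg)
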