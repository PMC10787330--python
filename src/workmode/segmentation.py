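"""Four-state day segmentation from probability + GPS.

Each evaluated minute is interpreted by crossing the final work-mode
probability with the GPS at-work indicator:

==============  ============  =====================
probability      GPS at work   state
==============  ============  =====================
> threshold      yes           office
<= threshold     yes           break_at_work
> threshold      no            remote
<= threshold     no            off
==============  ============  =====================

A probability exactly at the threshold goes to the non-working side (only
probabilities *higher* than the threshold count as on-working).  Episodes
are raw contiguous runs with no minimum-duration filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import EVAL_START_MIN, N_EVAL_MINUTES

STATE_NAMES = ("office", "break_at_work", "off", "remote")


@dataclass
class DaySegmentation:
    """Per-minute states over 05:45-24:00 plus derived episode list."""

    states: np.ndarray                       # array of state-name strings
    episodes: list                           # (state, start_min_of_day, end_min_of_day)
    totals_h: dict                           # state -> hours
    prob_work_h: float                       # office + remote
    gps_work_h: float                        # office + break


def classify_minutes(final: np.ndarray, gps: np.ndarray,
                     threshold: float = 0.5) -> DaySegmentation:
    """Cross probability and GPS series into the four states.

    Both series must share the 1095-minute evaluation grid.
    """
    final = np.asarray(final, dtype=float)
    gps = np.asarray(gps).astype(bool)
    if final.shape != gps.shape or len(final) != N_EVAL_MINUTES:
        raise ValueError("probability and GPS series must share the minute grid")
    on = final > threshold
    states = np.where(gps, np.where(on, "office", "break_at_work"),
                      np.where(on, "remote", "off"))
    episodes = []
    start = 0
    for i in range(1, len(states) + 1):
        if i == len(states) or states[i] != states[start]:
            episodes.append((str(states[start]), EVAL_START_MIN + start,
                             EVAL_START_MIN + i))
            start = i
    totals = {s: float(np.sum(states == s)) / 60.0 for s in STATE_NAMES}
    return DaySegmentation(
        states=states,
        episodes=episodes,
        totals_h=totals,
        prob_work_h=totals["office"] + totals["remote"],
        gps_work_h=totals["office"] + totals["break_at_work"],
    )


def summarize_day(seg: DaySegmentation) -> dict:
    """Daily totals in hours, plus the two work-hour definitions."""
    out = {f"{s}_h": seg.totals_h[s] for s in STATE_NAMES}
    out["prob_work_h"] = seg.prob_work_h
    out["gps_work_h"] = seg.gps_work_h
    return out
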