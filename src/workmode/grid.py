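"""Minute grid shared by every stage of the pipeline.

All per-minute series live on the evaluation span 05:45-24:00 local time
(1095 minutes).  Data between midnight and 05:45 are excluded throughout:
that span is dominated by sleep, and nocturnal non-use is easily confused
with non-use during work hours.
"""

from __future__ import annotations

from datetime import timedelta, timezone

#: first evaluated minute of day (05:45)
EVAL_START_MIN = 5 * 60 + 45
#: one past the last evaluated minute of day (24:00)
EVAL_END_MIN = 24 * 60
#: length of the evaluated span in minutes
N_EVAL_MINUTES = EVAL_END_MIN - EVAL_START_MIN  # 1095

SECONDS_PER_DAY = 86400

#: default local zone for wall-clock rules (UTC+8)
DEFAULT_TZ = timezone(timedelta(hours=8))


def minute_of_day(ts) -> int:
    """Minute-of-day (0..1439) of a timezone-aware timestamp."""
    return ts.hour * 60 + ts.minute


def eval_index(minute: int) -> int:
    """Index into the 1095-minute evaluation grid for a minute-of-day."""
    if not EVAL_START_MIN <= minute < EVAL_END_MIN:
        raise ValueError(f"minute {minute} outside evaluation span")
    return minute - EVAL_START_MIN
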