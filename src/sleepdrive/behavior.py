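"""Behavioral summaries: psychomotor vigilance task (PVT), Karolinska
Sleepiness Scale (KSS) pass-through, and actigraphy-derived sleep history.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PVTSummary", "SleepHistory",
    "summarize_pvt", "summarize_sleep", "estimate_rest_interval_fallback",
]

#: device system latency subtracted from every raw reaction time (ms)
DEFAULT_SYSTEM_LATENCY_MS = 82.0
#: adjusted reaction times strictly above this count as lapses (ms)
DEFAULT_LAPSE_THRESHOLD_MS = 500.0
#: activity-count cutoff for the diary-fallback bed/wake rule
FALLBACK_ACTIVITY_COUNT = 150.0


@dataclass
class PVTSummary:
    """Per-session PVT outcome: latency-adjusted mean RT and lapse count."""

    mean_rt_ms: float
    lapses: int
    n_trials: int
    system_latency_ms: float = DEFAULT_SYSTEM_LATENCY_MS
    lapse_threshold_ms: float = DEFAULT_LAPSE_THRESHOLD_MS


@dataclass
class SleepHistory:
    """Daily sleep durations (minutes) over the pre-study monitoring window."""

    daily_minutes: list[float] = field(default_factory=list)

    @property
    def mean_hours(self) -> float:
        return float(np.mean(self.daily_minutes)) / 60.0


def summarize_pvt(raw_rts_ms,
                  latency_ms: float = DEFAULT_SYSTEM_LATENCY_MS,
                  lapse_threshold_ms: float = DEFAULT_LAPSE_THRESHOLD_MS,
                  ) -> PVTSummary:
    """Summarize one PVT administration.

    Every raw reaction time is adjusted by subtracting the system latency;
    the summary reports the mean adjusted RT and the number of lapses,
    defined as adjusted RTs strictly greater than the threshold.
    """
    rts = np.asarray(list(raw_rts_ms), dtype=float)
    if rts.size == 0:
        raise ValueError("empty PVT trial list")
    if np.any(rts <= 0):
        raise ValueError("reaction times must be positive")
    adjusted = rts - latency_ms
    lapses = int(np.sum(adjusted > lapse_threshold_ms))
    return PVTSummary(float(adjusted.mean()), lapses, int(rts.size),
                      latency_ms, lapse_threshold_ms)


def summarize_sleep(epochs: pd.DataFrame,
                    rest_intervals: pd.DataFrame,
                    n_days: int = 14) -> SleepHistory:
    """Daily sleep totals from 1-minute pre-classified actigraphy epochs.

    Parameters
    ----------
    epochs : DataFrame with columns ``day`` (int), ``minute`` (int, minute
        index within that day's record) and ``is_sleep`` (bool); the
        sleep/wake classification is taken as given (device-scored).
    rest_intervals : DataFrame with columns ``day``, ``start_minute``,
        ``end_minute`` (half-open) and ``kind`` ("main" or "nap"); nap
        intervals are attributed to the ``day`` they carry.
    n_days : nominal monitoring window; fewer available days produce a
        warning, not an error.

    The daily total is the number of sleep-classified minutes inside that
    day's main rest interval plus its nap intervals, capped at 1440.
    """
    if rest_intervals is None or len(rest_intervals) == 0:
        raise ValueError("no rest intervals given; cannot attribute sleep")
    days = sorted(rest_intervals.loc[rest_intervals["kind"] == "main", "day"]
                  .unique())
    if len(days) < n_days:
        warnings.warn(
            f"only {len(days)} of {n_days} monitoring days have a main rest "
            "interval; averaging over available days"
        )
    daily: list[float] = []
    for day in days:
        total = 0
        day_epochs = epochs[epochs["day"] == day]
        for _, iv in rest_intervals[rest_intervals["day"] == day].iterrows():
            inside = day_epochs[
                (day_epochs["minute"] >= iv["start_minute"])
                & (day_epochs["minute"] < iv["end_minute"])
            ]
            total += int(inside["is_sleep"].sum())
        daily.append(min(float(total), 1440.0))
    return SleepHistory(daily)


def estimate_rest_interval_fallback(activity_counts,
                                    statuses,
                                    count_threshold: float = FALLBACK_ACTIVITY_COUNT,
                                    ) -> tuple[int | None, int | None]:
    """Estimate bed/wake times when the sleep diary is missing.

    Bedtime is the first 1-minute epoch whose activity count falls below
    the threshold while the epoch status is "sleep"; waketime is the first
    subsequent epoch whose count rises above the threshold while the status
    is "active".  Returns epoch indices, or ``None`` when no epoch
    qualifies.
    """
    counts = np.asarray(list(activity_counts), dtype=float)
    statuses = list(statuses)
    if counts.size != len(statuses):
        raise ValueError("activity counts and statuses must align")
    bedtime: int | None = None
    for i, (c, s) in enumerate(zip(counts, statuses)):
        if c < count_threshold and s == "sleep":
            bedtime = i
            break
    if bedtime is None:
        return None, None
    waketime: int | None = None
    for i in range(bedtime + 1, counts.size):
        if counts[i] > count_threshold and statuses[i] == "active":
            waketime = i
            break
    return bedtime, waketime
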