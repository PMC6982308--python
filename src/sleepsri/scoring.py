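"""Activity-count sleep/wake scoring and sleep-bout / nap detection.

The vendor scoring algorithm used by Actiwatch software is proprietary; this
module implements the published weighted-window stand-in: each epoch's score
is a symmetric weighted sum of activity counts over the epoch and its two
neighbours on each side (weights 1/25, 1/5, 1, 1/5, 1/25), and the epoch is
scored WAKE when the sum reaches the wake threshold (40, the "medium"
sensitivity setting), otherwise SLEEP.  EXCLUDED epochs are never scored and
contribute nothing: when the window overlaps an EXCLUDED epoch (or runs off
the end of the recording) the remaining weights are renormalised to the full
kernel mass so the threshold keeps its scale.

Naps are operationalised as scored sleep bouts that start within a daytime
clock window (08:00-20:00 by default) and last at least ``min_nap_minutes``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import datetime, timedelta

import numpy as np

from .io import EpochSeries, SleepState

__all__ = [
    "ScoringPolicy",
    "SleepBout",
    "score_states",
    "detect_bouts",
    "weekly_nap_minutes",
    "AllExcludedWarning",
]

DEFAULT_KERNEL = (1 / 25, 1 / 5, 1.0, 1 / 5, 1 / 25)


class AllExcludedWarning(UserWarning):
    """Raised (as a warning) when a series has no scoreable epochs."""


def _parse_clock(value: str | int | float) -> float:
    """Clock time as minutes past midnight; accepts 'HH:MM' or minutes."""
    if isinstance(value, str):
        h, m = value.split(":")
        return int(h) * 60 + int(m)
    return float(value)


@dataclass
class ScoringPolicy:
    """Parameters of the weighted-window scorer and the nap rule.

    kernel_weights : symmetric weights over the epoch and +-2 neighbours;
        the centre weight must be maximal.
    wake_threshold : weighted activity at or above which an epoch is WAKE.
    min_nap_minutes : shortest daytime sleep bout counted as a nap.
    nap_window_start / nap_window_end : clock window ('HH:MM' or minutes
        past midnight) within which a sleep bout's *start* makes it a nap.
    """

    kernel_weights: tuple[float, ...] = DEFAULT_KERNEL
    wake_threshold: float = 40.0
    min_nap_minutes: int = 10
    nap_window_start: str | float = "08:00"
    nap_window_end: str | float = "20:00"

    def __post_init__(self) -> None:
        w = tuple(float(x) for x in self.kernel_weights)
        if len(w) % 2 != 1:
            raise ValueError("kernel must have odd length")
        if w != w[::-1]:
            raise ValueError("kernel weights must be symmetric")
        if max(w) != w[len(w) // 2]:
            raise ValueError("centre kernel weight must be maximal")
        self.kernel_weights = w
        if self.wake_threshold <= 0:
            raise ValueError("wake_threshold must be positive")
        if self.min_nap_minutes <= 0:
            raise ValueError("min_nap_minutes must be positive")
        if self.nap_start_minutes >= self.nap_end_minutes:
            raise ValueError("nap window start must precede its end")

    @property
    def nap_start_minutes(self) -> float:
        return _parse_clock(self.nap_window_start)

    @property
    def nap_end_minutes(self) -> float:
        return _parse_clock(self.nap_window_end)

    def to_dict(self) -> dict:
        return {
            "kernel_weights": list(self.kernel_weights),
            "wake_threshold": self.wake_threshold,
            "min_nap_minutes": self.min_nap_minutes,
            "nap_window_start": self.nap_window_start,
            "nap_window_end": self.nap_window_end,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScoringPolicy":
        kw = dict(d)
        if "kernel_weights" in kw:
            kw["kernel_weights"] = tuple(kw["kernel_weights"])
        return cls(**kw)


@dataclass(frozen=True)
class SleepBout:
    """A maximal run of SLEEP epochs; ``is_nap`` marks qualifying daytime bouts."""

    start: datetime
    end: datetime
    minutes: int
    is_nap: bool

    def __post_init__(self) -> None:
        if self.minutes < 1:
            raise ValueError("a bout spans at least one minute")
        if (self.end - self.start) != timedelta(minutes=self.minutes):
            raise ValueError("minutes must equal end - start")


def weighted_activity(series: EpochSeries, policy: ScoringPolicy) -> np.ndarray:
    """Per-epoch weighted activity with EXCLUDED-aware renormalisation.

    Returns NaN at EXCLUDED epochs.  Where the window overlaps EXCLUDED
    epochs or the series boundary, available weights are rescaled so their
    mass equals the full kernel mass.
    """
    w = np.asarray(policy.kernel_weights, dtype=float)
    valid = (series.state != SleepState.EXCLUDED).astype(float)
    a = series.activity.astype(float) * valid
    num = np.convolve(a, w[::-1], mode="same")
    mass = np.convolve(valid, w[::-1], mode="same")
    full = w.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / mass * full
    out[valid == 0] = np.nan
    return out


def score_states(series: EpochSeries, policy: ScoringPolicy | None = None) -> EpochSeries:
    """Score every non-EXCLUDED epoch of ``series`` as WAKE or SLEEP.

    Returns a new series; EXCLUDED epochs are untouched.  A series with no
    scoreable epochs is returned unchanged with an :class:`AllExcludedWarning`.
    """
    policy = policy or ScoringPolicy()
    scorable = series.state != SleepState.EXCLUDED
    if not scorable.any():
        warnings.warn(
            f"{series.participant_id}: no scoreable epochs", AllExcludedWarning
        )
        return series.copy()
    W = weighted_activity(series, policy)
    out = series.copy()
    wake = W >= policy.wake_threshold
    out.state[scorable & wake] = SleepState.WAKE
    out.state[scorable & ~wake] = SleepState.SLEEP
    return out


def detect_bouts(
    series: EpochSeries, policy: ScoringPolicy | None = None
) -> list[SleepBout]:
    """Segment maximal runs of SLEEP epochs into bouts.

    EXCLUDED epochs break bouts (unknown state cannot be asserted asleep).
    A bout is a nap iff its start clock time lies within the policy's
    daytime window and its length is at least ``min_nap_minutes``; shorter
    daytime bouts are kept with ``is_nap=False``.
    """
    policy = policy or ScoringPolicy()
    asleep = series.state == SleepState.SLEEP
    if not asleep.any():
        return []
    padded = np.concatenate([[False], asleep, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    ep_min = series.epoch_seconds / 60.0
    clock = series.clock_minutes()
    ts = series.timestamps
    lo, hi = policy.nap_start_minutes, policy.nap_end_minutes
    bouts = []
    for s, e in zip(starts, ends):
        minutes = int(round((e - s) * ep_min))
        start_clock = clock[s]
        is_nap = (lo <= start_clock < hi) and minutes >= policy.min_nap_minutes
        start_dt = ts[s].to_pydatetime()
        bouts.append(
            SleepBout(
                start=start_dt,
                end=start_dt + timedelta(minutes=minutes),
                minutes=minutes,
                is_nap=is_nap,
            )
        )
    return bouts


def weekly_nap_minutes(
    bouts: list[SleepBout],
    series: EpochSeries,
    weeks: tuple[int, ...] = (1, 2, 3),
) -> dict[int, float | None]:
    """Total nap minutes per recording week (week k = days 7(k-1)+1 .. 7k).

    A nap is attributed to the week containing its start.  Weeks with no
    scored (non-EXCLUDED) day in the recording are None, not zero.
    """
    P = series.epochs_per_day
    scorable = series.state != SleepState.EXCLUDED
    out: dict[int, float | None] = {}
    for k in weeks:
        d0, d1 = 7 * (k - 1), 7 * k  # day indices, 0-based
        i0, i1 = d0 * P, min(d1 * P, series.n_epochs)
        if i0 >= series.n_epochs or not scorable[i0:i1].any():
            out[k] = None
            continue
        total = 0.0
        for b in bouts:
            if not b.is_nap:
                continue
            day = int((b.start - series.start).total_seconds() // 86400)
            if d0 <= day < d1:
                total += b.minutes
        out[k] = total
    return out
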