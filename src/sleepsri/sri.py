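"""The Sleep Regularity Index (SRI), eligibility filters and delta scores.

The SRI measures day-to-day stability of the sleep/wake pattern: for every
epoch pair 24 h apart whose states are both known, the pair *agrees* when the
state is identical.  The index rescales the mean agreement fraction A to

    SRI = 200 * A - 100

so a perfectly periodic sleeper scores 100 and a pattern whose days are
statistically independent scores near 0.  (The formula admits -100 for a
pattern that anti-repeats day over day; the index is reported un-clamped and
the theoretical floor is a documented curiosity, not an observable value in
real cohorts.)

Two averaging modes are provided:

``daily``  (default) — agreement is computed per day pair (day d vs day d+1)
    and the per-pair agreements are averaged, each day pair weighted equally
    regardless of how many of its epoch pairs are valid;
``pooled`` — all valid epoch pairs in the window are pooled and weighted
    equally.  The two coincide exactly whenever no epoch is EXCLUDED.

Eligibility mirrors the inpatient study design the defaults come from: a
participant needs at least 7 recorded days, and is dropped if any day within
the first 21 has 4 h or more of excluded data.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import EpochSeries, SleepState

__all__ = [
    "Window",
    "SriResult",
    "FilterPolicy",
    "DeltaSri",
    "DropReason",
    "day_pair_agreement",
    "compute_sri",
    "weekly_sris",
    "excluded_hours_by_day",
    "eligibility_filter",
    "missingness_report",
]


class Window(str, enum.Enum):
    """SRI averaging window: all days, or one recording week."""

    TOTAL = "TOTAL"
    WEEK1 = "WEEK1"
    WEEK2 = "WEEK2"
    WEEK3 = "WEEK3"

    @property
    def week(self) -> int | None:
        return None if self is Window.TOTAL else int(self.value[-1])


@dataclass(frozen=True)
class SriResult:
    """An SRI value with its window, agreement fraction and pair counts.

    ``sri`` is None when no valid epoch pair exists in the window.
    ``day_pairs_used`` counts day pairs contributing in daily mode.
    """

    window: Window
    sri: float | None
    agreement: float | None
    valid_pairs: int
    day_pairs_used: int

    def __post_init__(self) -> None:
        if self.valid_pairs == 0 and self.sri is not None:
            raise ValueError("sri must be null when no valid pairs exist")
        if self.sri is not None:
            if abs(self.sri - (200 * self.agreement - 100)) > 1e-9:
                raise ValueError("sri must equal 200*agreement - 100")


@dataclass
class FilterPolicy:
    """Participant eligibility thresholds.

    min_days : minimum recorded days (a day counts when it has at least one
        non-EXCLUDED epoch).
    max_excluded_hours_per_day : a day with at least this many excluded
        hours disqualifies the participant...
    horizon_days : ...when it falls within this many days of recording start.
    """

    min_days: int = 7
    max_excluded_hours_per_day: float = 4.0
    horizon_days: int = 21

    def __post_init__(self) -> None:
        if self.min_days <= 0 or self.max_excluded_hours_per_day <= 0 or self.horizon_days <= 0:
            raise ValueError("all FilterPolicy fields must be positive")

    def to_dict(self) -> dict:
        return {
            "min_days": self.min_days,
            "max_excluded_hours_per_day": self.max_excluded_hours_per_day,
            "horizon_days": self.horizon_days,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FilterPolicy":
        return cls(**d)


@dataclass(frozen=True)
class DeltaSri:
    """Week-over-week SRI changes; each None unless both weeks exist."""

    w2_minus_w1: float | None = None
    w3_minus_w2: float | None = None
    w3_minus_w1: float | None = None


class DropReason(str, enum.Enum):
    MIN_DAYS = "MIN_DAYS"
    EXCLUDED_HOURS = "EXCLUDED_HOURS"


# ---------------------------------------------------------------------------
# Core computation
# ---------------------------------------------------------------------------


def day_pair_agreement(
    series: EpochSeries, day: int
) -> tuple[float | None, int]:
    """Agreement between recording day ``day`` and the day that follows it.

    Over epochs t in day ``day`` for which both s_t and s_{t+P} are known
    (WAKE or SLEEP), returns the fraction with s_t == s_{t+P} and the count
    of such valid pairs.  A day pair with no valid pairs — including a day
    beyond the recording — yields (None, 0).
    """
    P = series.epochs_per_day
    s = series.state
    i0 = (day - 1) * P
    if day < 1 or i0 >= series.n_epochs:
        return None, 0
    i1 = min(day * P, series.n_epochs - P)
    if i1 <= i0:
        return None, 0
    a = s[i0:i1]
    b = s[i0 + P : i1 + P]
    valid = (a != SleepState.EXCLUDED) & (b != SleepState.EXCLUDED)
    n = int(valid.sum())
    if n == 0:
        return None, 0
    agree = int((a[valid] == b[valid]).sum())
    return agree / n, n


def _window_days(series: EpochSeries, window: Window) -> range:
    if window is Window.TOTAL:
        return range(1, series.n_days + 1)
    k = window.week
    return range(7 * (k - 1) + 1, 7 * k + 1)


def compute_sri(
    series: EpochSeries,
    window: Window | str = Window.TOTAL,
    mode: str = "daily",
) -> SriResult:
    """SRI of ``series`` over ``window``.

    Day pairs are attributed to the window containing their FIRST day, so
    week k uses pairs (d, d+1) for d in 7(k-1)+1 .. 7k.  Day pairs with no
    valid epoch pair are skipped; if none remain the result carries a null
    SRI rather than raising.

    ``mode='daily'`` averages per-day-pair agreements; ``mode='pooled'``
    pools all valid epoch pairs.  Both apply the 200*A - 100 transform.
    """
    window = Window(window)
    if mode not in ("daily", "pooled"):
        raise ValueError(f"unknown SRI mode {mode!r}")
    agreements: list[float] = []
    total_valid = 0
    total_agree = 0.0
    for d in _window_days(series, window):
        frac, n = day_pair_agreement(series, d)
        if frac is None:
            continue
        agreements.append(frac)
        total_valid += n
        total_agree += frac * n
    if not agreements:
        return SriResult(window, None, None, 0, 0)
    if mode == "daily":
        A = float(np.mean(agreements))
    else:
        A = total_agree / total_valid
    return SriResult(
        window=window,
        sri=200 * A - 100,
        agreement=A,
        valid_pairs=total_valid,
        day_pairs_used=len(agreements),
    )


def weekly_sris(
    series: EpochSeries, mode: str = "daily"
) -> tuple[dict[int, SriResult], DeltaSri]:
    """SRI for weeks 1-3 plus the week-over-week deltas.

    Weeks the recording does not reach carry null results, and any delta
    involving a null week is None.
    """
    weekly = {
        k: compute_sri(series, Window(f"WEEK{k}"), mode=mode) for k in (1, 2, 3)
    }
    v = {k: r.sri for k, r in weekly.items()}

    def diff(a: int, b: int) -> float | None:
        if v[a] is None or v[b] is None:
            return None
        return v[a] - v[b]

    return weekly, DeltaSri(
        w2_minus_w1=diff(2, 1),
        w3_minus_w2=diff(3, 2),
        w3_minus_w1=diff(3, 1),
    )


# ---------------------------------------------------------------------------
# Missingness accounting and eligibility
# ---------------------------------------------------------------------------


def excluded_hours_by_day(series: EpochSeries) -> dict[int, float]:
    """Hours of EXCLUDED data per recording day (1-based), partial last day
    counted as-is."""
    P = series.epochs_per_day
    out: dict[int, float] = {}
    excl = series.state == SleepState.EXCLUDED
    for d in range(1, series.n_days + 1):
        block = excl[(d - 1) * P : d * P]
        out[d] = float(block.sum()) * series.epoch_seconds / 3600.0
    return out


def recorded_days(series: EpochSeries) -> int:
    """Days with at least one non-EXCLUDED epoch."""
    P = series.epochs_per_day
    ok = series.state != SleepState.EXCLUDED
    n = 0
    for d in range(series.n_days):
        if ok[d * P : (d + 1) * P].any():
            n += 1
    return n


def eligibility_filter(
    cohort: Iterable[EpochSeries], policy: FilterPolicy | None = None
) -> tuple[list[str], dict[str, DropReason]]:
    """Apply the study's eligibility rules to a cohort.

    Checks run in a fixed order: first the minimum-days rule, then the
    excluded-hours-per-day rule within the horizon.  Returns the kept ids
    (input order) and a map of dropped id -> reason.
    """
    policy = policy or FilterPolicy()
    kept: list[str] = []
    dropped: dict[str, DropReason] = {}
    for series in cohort:
        if recorded_days(series) < policy.min_days:
            dropped[series.participant_id] = DropReason.MIN_DAYS
            continue
        hours = excluded_hours_by_day(series)
        over = any(
            h >= policy.max_excluded_hours_per_day
            for d, h in hours.items()
            if d <= policy.horizon_days
        )
        if over:
            dropped[series.participant_id] = DropReason.EXCLUDED_HOURS
        else:
            kept.append(series.participant_id)
    return kept, dropped


def missingness_report(
    cohort: Sequence[EpochSeries],
    thresholds: Sequence[float] = (2.0, 4.0, 6.0),
    horizon_days: int = 21,
) -> pd.DataFrame:
    """Sensitivity table: participants with >= h excluded hours on any day.

    For each threshold h, counts participants having at least h hours of
    excluded data on some day within the first ``horizon_days`` days.
    Counts are monotone non-increasing in h by construction.
    """
    worst = []
    for series in cohort:
        hours = excluded_hours_by_day(series)
        within = [h for d, h in hours.items() if d <= horizon_days]
        worst.append(max(within) if within else 0.0)
    worst_arr = np.asarray(worst)
    rows = [
        {"threshold_hours": float(h), "n_participants": int((worst_arr >= h).sum())}
        for h in thresholds
    ]
    return pd.DataFrame(rows)


def sri_results_frame(
    results: dict[str, dict[Window, SriResult]]
) -> pd.DataFrame:
    """Tidy per-participant SRI table:
    ``participant_id,window,sri,agreement,valid_pairs,day_pairs_used``."""
    rows = []
    for pid, by_window in results.items():
        for w, r in by_window.items():
            rows.append(
                {
                    "participant_id": pid,
                    "window": Window(w).value,
                    "sri": r.sri if r.sri is not None else math.nan,
                    "agreement": r.agreement if r.agreement is not None else math.nan,
                    "valid_pairs": r.valid_pairs,
                    "day_pairs_used": r.day_pairs_used,
                }
            )
    return pd.DataFrame(rows)
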