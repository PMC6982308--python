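"""Epoch-level actigraphy data model and CSV readers/writers.

An actigraphy record is a regular grid of fixed-length epochs (one minute by
default), each carrying an integrated activity count and, once scored, a
sleep/wake state.  Epochs with no valid data (off-wrist intervals, device
gaps) are EXCLUDED and are skipped by every downstream pair computation.

The grid is anchored at the first observed epoch; recording day ``d`` is the
half-open block of epochs ``[(d-1)*P, d*P)`` where ``P`` is the number of
epochs per day.  Days are recording days, not calendar days: inpatient
recordings start mid-day and nothing downstream anchors to midnight.
Timestamps are timezone-naive local clock time.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
import datetime as _dt
from datetime import datetime
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = [
    "SleepState",
    "EpochRecord",
    "EpochSeries",
    "DiaryDay",
    "read_epoch_csv",
    "write_epoch_csv",
    "read_diary_csv",
]


class SleepState(enum.IntEnum):
    """Per-epoch state. EXCLUDED marks off-wrist or otherwise invalid data."""

    WAKE = 0
    SLEEP = 1
    EXCLUDED = 2


_STATE_NAMES = {s.name: s for s in SleepState}


@dataclass(frozen=True)
class EpochRecord:
    """A single scoring epoch: timestamp, activity count, state, wear flag."""

    timestamp: datetime
    activity: int
    state: SleepState = SleepState.WAKE
    off_wrist: bool = False

    def __post_init__(self) -> None:
        if self.activity < 0:
            raise ValueError(f"activity must be non-negative, got {self.activity}")
        if self.off_wrist and self.state != SleepState.EXCLUDED:
            raise ValueError("off-wrist epochs must be EXCLUDED")


@dataclass
class EpochSeries:
    """One participant's ordered minute-epoch record.

    Stored as parallel numpy arrays over a strictly regular timestamp grid:
    ``timestamp(i) = start + i * epoch_seconds``.  Gaps must be represented
    as EXCLUDED epochs, never as absent rows, so that the 24-h lag used by
    the Sleep Regularity Index is pure index arithmetic (``t`` vs ``t + P``).
    """

    participant_id: str
    start: datetime
    activity: np.ndarray
    state: np.ndarray
    off_wrist: np.ndarray = None  # type: ignore[assignment]
    epoch_seconds: int = 60

    def __post_init__(self) -> None:
        self.activity = np.asarray(self.activity, dtype=np.int64)
        self.state = np.asarray(self.state, dtype=np.int8)
        if self.off_wrist is None:
            self.off_wrist = np.zeros(self.activity.shape, dtype=bool)
        self.off_wrist = np.asarray(self.off_wrist, dtype=bool)
        if not (len(self.activity) == len(self.state) == len(self.off_wrist)):
            raise ValueError("activity, state and off_wrist must have equal length")
        if self.epoch_seconds <= 0 or 86400 % self.epoch_seconds != 0:
            raise ValueError(
                f"epoch_seconds must divide 86400, got {self.epoch_seconds}"
            )
        if (self.activity < 0).any():
            raise ValueError("activity counts must be non-negative")
        if not np.isin(self.state, [0, 1, 2]).all():
            raise ValueError("state codes must be WAKE(0)/SLEEP(1)/EXCLUDED(2)")
        bad = self.off_wrist & (self.state != SleepState.EXCLUDED)
        if bad.any():
            raise ValueError("off-wrist epochs must have state EXCLUDED")

    # -- derived geometry ---------------------------------------------------

    @property
    def n_epochs(self) -> int:
        return len(self.activity)

    @property
    def epochs_per_day(self) -> int:
        """P: number of epochs in 24 h (1440 at the 60-s default)."""
        return 86400 // self.epoch_seconds

    @property
    def n_days(self) -> int:
        """Number of (possibly partial) recording days spanned."""
        P = self.epochs_per_day
        return -(-self.n_epochs // P)

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return pd.date_range(
            self.start, periods=self.n_epochs, freq=f"{self.epoch_seconds}s"
        )

    def day_slice(self, day: int) -> slice:
        """Index slice of recording day ``day`` (1-based)."""
        if day < 1:
            raise ValueError("day is 1-based")
        P = self.epochs_per_day
        return slice((day - 1) * P, day * P)

    def clock_minutes(self) -> np.ndarray:
        """Minutes past midnight of each epoch's timestamp."""
        start_min = self.start.hour * 60 + self.start.minute
        step = self.epoch_seconds / 60.0
        return (start_min + np.arange(self.n_epochs) * step) % 1440

    # -- conversion ---------------------------------------------------------

    def records(self) -> Iterator[EpochRecord]:
        for ts, a, s, ow in zip(
            self.timestamps, self.activity, self.state, self.off_wrist
        ):
            yield EpochRecord(ts.to_pydatetime(), int(a), SleepState(int(s)), bool(ow))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timestamp": self.timestamps,
                "activity": self.activity,
                "state": [SleepState(int(s)).name for s in self.state],
                "off_wrist": self.off_wrist,
            }
        )

    def copy(self) -> "EpochSeries":
        return replace(
            self,
            activity=self.activity.copy(),
            state=self.state.copy(),
            off_wrist=self.off_wrist.copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EpochSeries):
            return NotImplemented
        return (
            self.participant_id == other.participant_id
            and self.start == other.start
            and self.epoch_seconds == other.epoch_seconds
            and np.array_equal(self.activity, other.activity)
            and np.array_equal(self.state, other.state)
            and np.array_equal(self.off_wrist, other.off_wrist)
        )


@dataclass(frozen=True)
class DiaryDay:
    """One day of the self-reported sleep & symptom diary.

    Exhaustion is rated each evening on a 0-10 visual analog scale; missing
    fields stay None (never silently zero).
    """

    participant_id: str
    date: _dt.date
    n_awakenings: int | None = None
    n_naps_reported: int | None = None
    caffeinated_drinks: int | None = None
    mental_exhaustion: float | None = None
    physical_exhaustion: float | None = None

    def __post_init__(self) -> None:
        for name in ("mental_exhaustion", "physical_exhaustion"):
            v = getattr(self, name)
            if v is not None and not (0 <= v <= 10):
                raise ValueError(f"{name} must lie in [0, 10], got {v}")


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

#: Marker line terminating the metadata preamble of an Actiware-style export.
ACTIWARE_MARKER = "---- Epoch-by-Epoch Data ----"

_ACTIWARE_COLUMNS = {
    "timestamp": "timestamp",
    "activity": "activity",
    "state": "state",
    "off_wrist": "off_wrist",
}


def read_epoch_csv(
    path: str | Path,
    dialect: str = "plain",
    participant_id: str | None = None,
    columns: dict[str, str] | None = None,
) -> EpochSeries:
    """Read a per-participant epoch CSV into a validated :class:`EpochSeries`.

    Parameters
    ----------
    path
        CSV file with at least timestamp and activity columns.  Optional
        ``state`` and ``off_wrist`` columns are honoured.
    dialect
        ``"plain"`` — header + data rows; ``"actiware_export"`` — a metadata
        preamble terminated by :data:`ACTIWARE_MARKER` precedes the epoch
        table, and column names may be remapped via ``columns``.
    participant_id
        Defaults to the file stem.
    columns
        For ``actiware_export``: mapping of logical names
        (``timestamp``/``activity``/``state``/``off_wrist``) to the column
        names actually present in the export.

    Gaps in the timestamp grid are filled with EXCLUDED epochs so spacing
    stays constant; timestamps not on the grid raise a structural error.
    """
    path = Path(path)
    if dialect not in ("plain", "actiware_export"):
        raise ValueError(f"unknown dialect {dialect!r}")
    skiprows = 0
    if dialect == "actiware_export":
        with open(path) as fh:
            for i, line in enumerate(fh):
                if line.strip() == ACTIWARE_MARKER:
                    skiprows = i + 1
                    break
            else:
                raise ValueError(
                    f"{path}: no {ACTIWARE_MARKER!r} marker line found"
                )
    df = pd.read_csv(path, skiprows=skiprows)
    if dialect == "actiware_export":
        colmap = dict(_ACTIWARE_COLUMNS)
        if columns:
            colmap.update(columns)
        rename = {v: k for k, v in colmap.items() if v in df.columns}
        df = df.rename(columns=rename)
    if "timestamp" not in df.columns or "activity" not in df.columns:
        raise ValueError(f"{path}: needs 'timestamp' and 'activity' columns")

    try:
        ts = pd.to_datetime(df["timestamp"], format="ISO8601")
    except (ValueError, TypeError):
        # locate the offending row for a useful message
        for i, raw in enumerate(df["timestamp"]):
            try:
                pd.to_datetime(raw)
            except (ValueError, TypeError):
                raise ValueError(
                    f"{path}: malformed timestamp {raw!r} at data row {i}"
                ) from None
        raise
    if df.empty:
        return EpochSeries(
            participant_id=participant_id or path.stem,
            start=datetime(2000, 1, 1),
            activity=np.zeros(0, dtype=np.int64),
            state=np.zeros(0, dtype=np.int8),
        )
    if not ts.is_monotonic_increasing or ts.duplicated().any():
        raise ValueError(f"{path}: timestamps must be strictly increasing")

    # infer epoch length from the smallest positive spacing
    if len(ts) > 1:
        step = int(ts.diff().dropna().dt.total_seconds().min())
    else:
        step = 60
    if step <= 0 or 86400 % step != 0:
        raise ValueError(f"{path}: inferred epoch of {step}s does not divide a day")
    offsets = (ts - ts.iloc[0]).dt.total_seconds()
    if (offsets % step != 0).any():
        raise ValueError(f"{path}: timestamps are not on a regular {step}-s grid")

    n = int(offsets.iloc[-1] // step) + 1
    idx = (offsets // step).astype(int).to_numpy()
    activity = np.zeros(n, dtype=np.int64)
    state = np.full(n, SleepState.EXCLUDED, dtype=np.int8)
    off_wrist = np.ones(n, dtype=bool)

    activity[idx] = df["activity"].to_numpy()
    if "state" in df.columns:
        st = df["state"].map(lambda s: _STATE_NAMES[str(s).upper()]).to_numpy()
    else:
        st = np.zeros(len(df), dtype=np.int8)  # unscored: provisional WAKE
    state[idx] = st
    if "off_wrist" in df.columns:
        ow = df["off_wrist"].astype(bool).to_numpy()
    else:
        ow = np.zeros(len(df), dtype=bool)
    off_wrist[idx] = ow
    state[idx[ow]] = SleepState.EXCLUDED

    return EpochSeries(
        participant_id=participant_id or path.stem,
        start=ts.iloc[0].to_pydatetime(),
        activity=activity,
        state=state,
        off_wrist=off_wrist,
        epoch_seconds=step,
    )


def write_epoch_csv(series: EpochSeries, path: str | Path) -> Path:
    """Write ``series`` as a plain-dialect CSV (header ``timestamp,activity,
    state,off_wrist``, ISO-8601 timestamps, one row per epoch in grid order).

    ``read_epoch_csv(write_epoch_csv(s)) == s`` for any valid series.
    """
    path = Path(path)
    df = series.to_frame()
    df["timestamp"] = df["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    df["off_wrist"] = df["off_wrist"].astype(bool)
    df.to_csv(path, index=False)
    return path


_DIARY_INT_FIELDS = ("n_awakenings", "n_naps_reported", "caffeinated_drinks")
_DIARY_FLOAT_FIELDS = ("mental_exhaustion", "physical_exhaustion")


def read_diary_csv(path: str | Path) -> list[DiaryDay]:
    """Read a daily sleep & symptom diary CSV into :class:`DiaryDay` rows.

    Requires ``participant_id`` and ``date`` columns plus at least one diary
    field; missing cells become None, never zeros.  Exhaustion scores outside
    [0, 10] raise a validation error.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        return []
    if "participant_id" not in df.columns or "date" not in df.columns:
        raise ValueError(f"{path}: needs 'participant_id' and 'date' columns")
    known = set(_DIARY_INT_FIELDS) | set(_DIARY_FLOAT_FIELDS)
    if not known & set(df.columns):
        raise ValueError(f"{path}: no diary fields among {sorted(known)}")
    out: list[DiaryDay] = []
    for _, row in df.iterrows():
        kwargs: dict = {
            "participant_id": str(row["participant_id"]),
            "date": pd.to_datetime(row["date"]).date(),
        }
        for f in _DIARY_INT_FIELDS:
            if f in df.columns and pd.notna(row[f]):
                kwargs[f] = int(row[f])
        for f in _DIARY_FLOAT_FIELDS:
            if f in df.columns and pd.notna(row[f]):
                kwargs[f] = float(row[f])
        out.append(DiaryDay(**kwargs))
    return out
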