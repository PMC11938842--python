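"""Canonical data model for chamber sensor streams.

A :class:`SensorSeries` lives on a complete, regular one-minute grid with an
explicit missing mask — missingness is never encoded with sentinel values
because downstream imputation branches on it.  Raw high-cadence readings are
held in :class:`RawReadings` and reduced to the minute grid by
:func:`minute_average`.  Binary door/person activity is held in
:class:`EventLog` as a normalized sequence of state transitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EVENT_CHANNELS",
    "EventLog",
    "RawReadings",
    "SensorSeries",
    "TrialConfig",
    "minute_grid",
    "minute_average",
    "read_sensor_log",
    "write_sensor_log",
    "read_event_log",
    "write_event_log",
]

EVENT_CHANNELS = ("door", "person_1", "person_2", "person_3")

_MINUTE = pd.Timedelta(minutes=1)


def minute_grid(start, end) -> pd.DatetimeIndex:
    """Complete 1-minute grid over the half-open window [start, end)."""
    start = pd.Timestamp(start)
    end = pd.Timestamp(end)
    if start >= end:
        raise ValueError(f"empty window: [{start}, {end})")
    if start != start.floor("min") or end != end.floor("min"):
        raise ValueError("window boundaries must fall on whole minutes")
    return pd.date_range(start, end, freq="min", inclusive="left")


def _check_minute_grid(timestamps: pd.DatetimeIndex) -> None:
    if len(timestamps) == 0:
        raise ValueError("empty timestamp grid")
    if timestamps.has_duplicates:
        raise ValueError("duplicate timestamps in grid")
    diffs = np.diff(timestamps.asi8)
    if len(diffs) and not np.all(diffs == 60_000_000_000):
        raise ValueError("timestamps are not a complete regular 1-minute grid")


@dataclass
class SensorSeries:
    """One sensor's values on a regular minute grid with an explicit mask."""

    sensor_id: str
    trial_id: str
    timestamps: pd.DatetimeIndex
    values: np.ndarray
    missing_mask: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        _check_minute_grid(self.timestamps)
        n = len(self.timestamps)
        if len(self.values) != n or len(self.missing_mask) != n:
            raise ValueError("values/mask length mismatch with grid")
        observed = self.values[~self.missing_mask]
        if observed.size and not np.all(np.isfinite(observed)):
            raise ValueError("non-missing values must be finite")
        # mask true <=> value absent; keep NaN under the mask for safety
        self.values = self.values.copy()
        self.values[self.missing_mask] = np.nan

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def window(self) -> tuple[pd.Timestamp, pd.Timestamp]:
        return self.timestamps[0], self.timestamps[-1] + _MINUTE

    @property
    def n_missing(self) -> int:
        return int(self.missing_mask.sum())

    def slot_of_day(self) -> np.ndarray:
        """hh:mm slot index (0..1439) of every grid minute."""
        return (self.timestamps.hour * 60 + self.timestamps.minute).to_numpy()

    def slice_window(self, start, end) -> "SensorSeries":
        grid = minute_grid(start, end)
        sel = (self.timestamps >= grid[0]) & (self.timestamps <= grid[-1])
        if sel.sum() != len(grid):
            raise ValueError("requested window not covered by series")
        return SensorSeries(
            self.sensor_id,
            self.trial_id,
            self.timestamps[sel],
            self.values[np.asarray(sel)],
            self.missing_mask[np.asarray(sel)],
        )

    @classmethod
    def from_values(cls, sensor_id, trial_id, timestamps, values) -> "SensorSeries":
        """Build from a value array where NaN marks missing."""
        values = np.asarray(values, dtype=float)
        return cls(sensor_id, trial_id, timestamps, values, np.isnan(values))


@dataclass
class RawReadings:
    """High-cadence (e.g. 10 s) readings before minute averaging."""

    sensor_id: str
    timestamps: pd.DatetimeIndex
    values: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.timestamps) != len(self.values):
            raise ValueError("timestamps/values length mismatch")
        if len(self.timestamps) > 1 and (np.diff(self.timestamps.asi8) < 0).any():
            raise ValueError("raw timestamps must be non-decreasing")
        bad = ~np.isfinite(self.values)
        if bad.any():
            first = self.timestamps[int(np.argmax(bad))]
            raise ValueError(f"non-finite raw value at {first}")

    def __len__(self) -> int:
        return len(self.timestamps)


@dataclass
class EventLog:
    """Normalized binary state transitions for one activity channel.

    States alternate: after normalization there are no repeated identical
    consecutive states, and the implicit initial state is 0.
    """

    channel: str
    timestamps: pd.DatetimeIndex
    states: np.ndarray

    def __post_init__(self) -> None:
        if self.channel not in EVENT_CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.states = np.asarray(self.states, dtype=int)
        if len(self.timestamps) != len(self.states):
            raise ValueError("timestamps/states length mismatch")
        if not np.isin(self.states, (0, 1)).all():
            raise ValueError("states must be 0 or 1")
        if len(self.timestamps) > 1 and (np.diff(self.timestamps.asi8) < 0).any():
            raise ValueError("event timestamps must be non-decreasing")
        if len(self.states) and (np.diff(self.states) == 0).any():
            raise ValueError("states must alternate (normalize first)")
        if len(self.states) and self.states[0] != 1:
            raise ValueError("first transition must be 0 -> 1")

    def __len__(self) -> int:
        return len(self.timestamps)

    def intervals(self, end=None) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
        """Half-open 'active' intervals; an unterminated 1 closes at `end`."""
        out: list[tuple[pd.Timestamp, pd.Timestamp]] = []
        open_at: pd.Timestamp | None = None
        for t, s in zip(self.timestamps, self.states):
            if s == 1:
                open_at = t
            else:
                out.append((open_at, t))
                open_at = None
        if open_at is not None:
            if end is None:
                raise ValueError(
                    f"channel {self.channel}: unterminated interval and no window end"
                )
            out.append((open_at, pd.Timestamp(end)))
        return out

    @classmethod
    def from_raw(cls, channel: str, timestamps, states) -> "EventLog":
        """Normalize a raw event sequence: collapse repeated identical states.

        The implicit initial state is 0, so leading 0 records are dropped and
        repeated 1s (or 0s) keep only the first occurrence.
        """
        timestamps = pd.DatetimeIndex(timestamps)
        states = np.asarray(states, dtype=int)
        if not np.isin(states, (0, 1)).all():
            raise ValueError("states must be 0 or 1")
        order = np.argsort(timestamps.asi8, kind="stable")
        timestamps, states = timestamps[order], states[order]
        keep_t, keep_s = [], []
        current = 0
        for t, s in zip(timestamps, states):
            if s != current:
                keep_t.append(t)
                keep_s.append(s)
                current = s
        return cls(channel, pd.DatetimeIndex(keep_t), np.asarray(keep_s, dtype=int))


@dataclass
class TrialConfig:
    """Setpoint schedule and windows for one temperature trial."""

    trial_id: str
    day_setpoint: float
    night_setpoint: float
    day_hours: float
    night_hours: float
    window: tuple
    analysis_window: tuple | None = None
    day_start: str = "06:00"

    def __post_init__(self) -> None:
        if abs(self.day_hours + self.night_hours - 24.0) > 1e-9:
            raise ValueError("day_hours + night_hours must equal 24")
        self.window = (pd.Timestamp(self.window[0]), pd.Timestamp(self.window[1]))
        if self.analysis_window is None:
            self.analysis_window = self.window
        else:
            self.analysis_window = (
                pd.Timestamp(self.analysis_window[0]),
                pd.Timestamp(self.analysis_window[1]),
            )
        if not (
            self.window[0] <= self.analysis_window[0]
            and self.analysis_window[1] <= self.window[1]
        ):
            raise ValueError("analysis_window must lie inside window")


def minute_average(
    raw: RawReadings, window, trial_id: str = ""
) -> SensorSeries:
    """Reduce raw readings to one arithmetic mean per minute bin [t, t+1min).

    Minutes containing zero readings are marked missing.  The output grid
    covers `window` exactly.
    """
    grid = minute_grid(*window)
    values = np.full(len(grid), np.nan)
    if len(raw) > 0:
        floored = raw.timestamps.floor("min")
        s = pd.Series(raw.values, index=floored)
        means = s.groupby(level=0).mean()
        means = means[(means.index >= grid[0]) & (means.index <= grid[-1])]
        pos = ((means.index.asi8 - grid[0].value) // 60_000_000_000).astype(int)
        values[pos] = means.to_numpy()
    return SensorSeries.from_values(raw.sensor_id, trial_id, grid, values)


# ---------------------------------------------------------------------------
# CSV readers / writers
# ---------------------------------------------------------------------------

_SENSOR_COLUMNS = ["timestamp", "sensor_id", "value_c"]
_EVENT_COLUMNS = ["timestamp", "channel", "state"]


def _parse_timestamps(raw: pd.Series, path) -> pd.DatetimeIndex:
    parsed = pd.to_datetime(raw, format="ISO8601", errors="coerce")
    bad = parsed.isna() & raw.notna()
    if bad.any():
        row = int(np.argmax(bad.to_numpy())) + 2  # 1-based, plus header line
        raise ValueError(f"{path}: unparseable timestamp at row {row}: {raw[bad].iloc[0]!r}")
    return pd.DatetimeIndex(parsed)


def read_sensor_log(path, trial_id: str = "", window=None) -> list[SensorSeries]:
    """Read a `timestamp,sensor_id,value_c` CSV into per-sensor minute series.

    Rows are partitioned by sensor; after alignment to the minute grid any
    gaps become missing.  If `window` is omitted each sensor's grid spans its
    own first to last observed minute (inclusive).
    """
    df = pd.read_csv(path, dtype={"sensor_id": str}, float_precision="round_trip")
    if list(df.columns) != _SENSOR_COLUMNS:
        raise ValueError(
            f"{path}: expected columns {_SENSOR_COLUMNS}, found {list(df.columns)}"
        )
    ts = _parse_timestamps(df["timestamp"], path)
    df = df.assign(timestamp=ts)
    dup = df.duplicated(subset=["sensor_id", "timestamp"])
    if dup.any():
        row = int(np.argmax(dup.to_numpy())) + 2
        raise ValueError(f"{path}: duplicate (sensor, timestamp) at row {row}")
    out: list[SensorSeries] = []
    for sensor_id, grp in df.groupby("sensor_id", sort=True):
        grp = grp.sort_values("timestamp")
        if window is not None:
            grid = minute_grid(*window)
        else:
            grid = minute_grid(
                grp["timestamp"].iloc[0].floor("min"),
                grp["timestamp"].iloc[-1].floor("min") + _MINUTE,
            )
        values = np.full(len(grid), np.nan)
        pos = ((grp["timestamp"].dt.floor("min").astype("int64") - grid[0].value)
               // 60_000_000_000).to_numpy()
        inside = (pos >= 0) & (pos < len(grid))
        values[pos[inside]] = grp["value_c"].to_numpy()[inside]
        out.append(SensorSeries.from_values(str(sensor_id), trial_id, grid, values))
    return out


def write_sensor_log(series: Iterable[SensorSeries], path) -> None:
    """Write non-missing rows of one or more series as sensor-log CSV."""
    frames = []
    for s in series:
        keep = ~s.missing_mask
        frames.append(
            pd.DataFrame(
                {
                    "timestamp": s.timestamps[keep].strftime("%Y-%m-%dT%H:%M:%S"),
                    "sensor_id": s.sensor_id,
                    # shortest round-trip repr => bit-exact re-read
                    "value_c": [repr(float(v)) for v in s.values[keep]],
                }
            )
        )
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=_SENSOR_COLUMNS
    )
    df.to_csv(path, index=False)


def read_event_log(path, window_end=None) -> list[EventLog]:
    """Read a `timestamp,channel,state` CSV into normalized per-channel logs.

    Repeated identical states are collapsed; if `window_end` is given, a
    final unterminated 'open/present' state is closed at the window end.
    Channels absent from the file yield empty logs (permanently 0).
    """
    df = pd.read_csv(path)
    if df.empty and list(df.columns) != _EVENT_COLUMNS:
        df = pd.DataFrame(columns=_EVENT_COLUMNS)
    if list(df.columns) != _EVENT_COLUMNS:
        raise ValueError(
            f"{path}: expected columns {_EVENT_COLUMNS}, found {list(df.columns)}"
        )
    if not df.empty and not df["state"].isin((0, 1)).all():
        bad = ~df["state"].isin((0, 1))
        row = int(np.argmax(bad.to_numpy())) + 2
        raise ValueError(f"{path}: state not in {{0,1}} at row {row}")
    logs: list[EventLog] = []
    for channel in EVENT_CHANNELS:
        grp = df[df["channel"] == channel] if not df.empty else df
        if grp.empty:
            logs.append(EventLog(channel, pd.DatetimeIndex([]), np.array([], dtype=int)))
            continue
        ts = _parse_timestamps(grp["timestamp"].reset_index(drop=True), path)
        log = EventLog.from_raw(channel, ts, grp["state"].to_numpy())
        if window_end is not None and len(log) and log.states[-1] == 1:
            log = EventLog(
                channel,
                log.timestamps.append(pd.DatetimeIndex([pd.Timestamp(window_end)])),
                np.append(log.states, 0),
            )
        logs.append(log)
    return logs


def write_event_log(logs: Iterable[EventLog], path) -> None:
    frames = []
    for log in logs:
        if len(log) == 0:
            continue
        frames.append(
            pd.DataFrame(
                {
                    "timestamp": log.timestamps.strftime("%Y-%m-%dT%H:%M:%S"),
                    "channel": log.channel,
                    "state": log.states,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=_EVENT_COLUMNS
    )
    df = df.sort_values(["timestamp", "channel"], kind="stable")
    df.to_csv(path, index=False)
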