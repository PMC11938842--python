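"""Per-minute operation intensity and the cumulative Agr.Ops covariate.

Door and person event logs are rasterized onto the minute grid: a minute is
door-open if the door is open for any part of it, and the person count is
the number of person channels present at the minute's start.  Intensity is a
weighted combination (default: person-minutes with multiplicity, door weight
zero) and the covariate is its running sum from trial start.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .timeseries import EventLog, minute_grid

__all__ = ["AgrOpsWeights", "AgrOpsSeries", "events_to_minutes", "cumulative_agr_ops"]


@dataclass(frozen=True)
class AgrOpsWeights:
    person: float = 1.0
    door: float = 0.0

    def __post_init__(self) -> None:
        if self.person < 0 or self.door < 0:
            raise ValueError("weights must be non-negative")


@dataclass
class AgrOpsSeries:
    timestamps: pd.DatetimeIndex
    person_count: np.ndarray
    door_open: np.ndarray
    intensity: np.ndarray | None = None
    cumulative: np.ndarray | None = None
    weights: AgrOpsWeights | None = None

    def __post_init__(self) -> None:
        self.person_count = np.asarray(self.person_count, dtype=int)
        self.door_open = np.asarray(self.door_open, dtype=int)
        if (self.person_count > 3).any():
            raise ValueError("person_count cannot exceed 3")

    def __len__(self) -> int:
        return len(self.timestamps)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timestamp": self.timestamps,
                "person_count": self.person_count,
                "door_open": self.door_open,
                "intensity": self.intensity,
                "cumulative": self.cumulative,
            }
        )


def _minute_positions(grid: pd.DatetimeIndex, t: pd.Timestamp) -> float:
    return (t.value - grid[0].value) / 60_000_000_000


def events_to_minutes(logs: list[EventLog], window) -> AgrOpsSeries:
    """Rasterize normalized event logs onto the minute grid of `window`."""
    grid = minute_grid(*window)
    n = len(grid)
    person = np.zeros(n, dtype=int)
    door = np.zeros(n, dtype=int)
    end = grid[-1] + pd.Timedelta(minutes=1)
    for log in logs:
        intervals = log.intervals(end=end)
        # reject overlapping intervals on one channel
        for (a0, a1), (b0, b1) in zip(intervals, intervals[1:]):
            if b0 < a1:
                raise ValueError(f"overlapping intervals on channel {log.channel}")
        for s, e in intervals:
            if log.channel == "door":
                # open during any part of minute [m, m+1)
                lo = int(np.floor(_minute_positions(grid, s)))
                hi = int(np.ceil(_minute_positions(grid, e)))
                lo, hi = max(lo, 0), min(hi, n)
                if lo < hi:
                    door[lo:hi] = 1
            else:
                # present at the minute's start: s <= m < e
                lo = int(np.ceil(_minute_positions(grid, s)))
                hi = int(np.ceil(_minute_positions(grid, e)))
                lo, hi = max(lo, 0), min(hi, n)
                if lo < hi:
                    person[lo:hi] += 1
    return AgrOpsSeries(grid, person, door)


def cumulative_agr_ops(
    series: AgrOpsSeries, weights: AgrOpsWeights = AgrOpsWeights()
) -> AgrOpsSeries:
    """Weighted per-minute intensity and its prefix sum from trial start."""
    intensity = weights.person * series.person_count + weights.door * series.door_open
    return AgrOpsSeries(
        timestamps=series.timestamps,
        person_count=series.person_count,
        door_open=series.door_open,
        intensity=intensity.astype(float),
        cumulative=np.cumsum(intensity, dtype=float),
        weights=weights,
    )
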