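"""Seeded synthetic chamber: diurnal square-wave temperature streams, event
logs, block missingness and planted anomalies with ground-truth labels.

The base signal alternates between day and night setpoints on the trial's
photoperiod, approaching each new setpoint exponentially with a per-sensor
time constant (zero lag = instantaneous square wave).  Per-sensor bias and
iid Gaussian noise are added on top, then anomalies are superposed:

========================  ====================================================
kind                      effect
========================  ====================================================
``door_bump``             additive bump + door-open event over the window
``occupancy_bump``        additive bump + person-presence event
``sensor_drift``          linear ramp from 0 to `magnitude` across duration
``power_outage``          whole block masked missing
``power_surge_spike``     additive spike (default one minute)
``ac_delay``              setpoint schedule delayed by `magnitude` minutes
========================  ====================================================

Every anomalous (minute, sensor) pair is emitted in the label table, so
detection metrics can be computed against ground truth.  One global seed
governs all streams; per-(sensor, trial) substreams are derived from stable
integer offsets so adding a sensor leaves existing streams unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .timeseries import (
    EventLog,
    RawReadings,
    SensorSeries,
    TrialConfig,
    minute_grid,
)

__all__ = [
    "SensorSpec",
    "AnomalyEvent",
    "MissingBlock",
    "SimConfig",
    "SimResult",
    "DetectionMetrics",
    "default_trial_plan",
    "simulate_chamber",
    "simulate_raw",
    "labels_to_truth",
]

ANOMALY_KINDS = (
    "door_bump",
    "occupancy_bump",
    "sensor_drift",
    "power_outage",
    "power_surge_spike",
    "ac_delay",
)

DEFAULT_DAY_SETPOINTS = (30.0, 24.0, 28.0, 26.0)  # trials T1..T4
DEFAULT_NIGHT_OFFSET = 6.0
DAY_HOURS = 16.5
NIGHT_HOURS = 7.5


@dataclass(frozen=True)
class SensorSpec:
    sensor_id: str
    bias: float = 0.0
    noise_sd: float = 0.1
    transition_lag_min: float = 0.0


@dataclass(frozen=True)
class AnomalyEvent:
    kind: str
    start: pd.Timestamp
    duration_min: int
    magnitude: float  # °C, or minutes for ac_delay
    sensors: tuple[str, ...] | None = None  # None = all sensors

    def __post_init__(self) -> None:
        if self.kind not in ANOMALY_KINDS:
            raise ValueError(f"unknown anomaly kind {self.kind!r}")
        object.__setattr__(self, "start", pd.Timestamp(self.start))
        if self.duration_min < 1:
            raise ValueError("duration must be at least one minute")


@dataclass(frozen=True)
class MissingBlock:
    """Benign (unlabelled) block missingness, e.g. connectivity gaps."""

    start: pd.Timestamp
    duration_min: int
    sensors: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "start", pd.Timestamp(self.start))


@dataclass
class SimConfig:
    trials: list[TrialConfig]
    sensors: list[SensorSpec]
    anomalies: list[AnomalyEvent] = field(default_factory=list)
    missing_blocks: list[MissingBlock] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        for s in self.sensors:
            if s.noise_sd < 0:
                raise ValueError("noise_sd must be non-negative")


@dataclass
class SimResult:
    series: list[SensorSeries]  # one per (trial, sensor)
    events: list[EventLog]
    labels: pd.DataFrame  # timestamp, sensor_id, trial_id, kind

    def get_series(self, sensor_id: str, trial_id: str) -> SensorSeries:
        for s in self.series:
            if s.sensor_id == sensor_id and s.trial_id == trial_id:
                return s
        raise KeyError((sensor_id, trial_id))


def default_trial_plan(
    start="2021-03-01",
    trial_days: int = 35,
    analysis_skip_days: int = 7,
    day_setpoints=DEFAULT_DAY_SETPOINTS,
    night_offset: float = DEFAULT_NIGHT_OFFSET,
) -> list[TrialConfig]:
    """Four back-to-back 35-day trials; analysis window = weeks 2-5."""
    start = pd.Timestamp(start)
    analysis_skip_days = max(0, min(analysis_skip_days, trial_days - 1))
    trials = []
    for i, day_sp in enumerate(day_setpoints, start=1):
        t0 = start + pd.Timedelta(days=(i - 1) * trial_days)
        t1 = t0 + pd.Timedelta(days=trial_days)
        trials.append(
            TrialConfig(
                trial_id=f"T{i}",
                day_setpoint=day_sp,
                night_setpoint=day_sp - night_offset,
                day_hours=DAY_HOURS,
                night_hours=NIGHT_HOURS,
                window=(t0, t1),
                analysis_window=(t0 + pd.Timedelta(days=analysis_skip_days), t1),
            )
        )
    return trials


def _setpoint_profile(trial: TrialConfig, grid: pd.DatetimeIndex) -> np.ndarray:
    """Nominal setpoint at each grid minute (square wave on the photoperiod)."""
    h, m = map(int, trial.day_start.split(":"))
    day_start_min = h * 60 + m
    day_len_min = round(trial.day_hours * 60)
    tod = (grid.hour * 60 + grid.minute).to_numpy()
    in_day = ((tod - day_start_min) % 1440) < day_len_min
    return np.where(in_day, trial.day_setpoint, trial.night_setpoint)


def _lagged_response(setpoints: np.ndarray, lag_min: float, initial: float) -> np.ndarray:
    """First-order exponential approach toward a stepping setpoint."""
    if lag_min <= 0:
        return setpoints.astype(float)
    decay = np.exp(-1.0 / lag_min)
    out = np.empty(len(setpoints))
    prev = initial
    for i, sp in enumerate(setpoints):
        prev = sp + (prev - sp) * decay
        out[i] = prev
    return out


def _block_slice(grid: pd.DatetimeIndex, start: pd.Timestamp, duration_min: int):
    lo = int((pd.Timestamp(start).value - grid[0].value) // 60_000_000_000)
    hi = lo + duration_min
    return max(lo, 0), min(hi, len(grid))


def _affects(ev, sensor_id: str) -> bool:
    return ev.sensors is None or sensor_id in ev.sensors


def simulate_chamber(cfg: SimConfig) -> SimResult:
    """Generate per-(trial, sensor) minute series, event logs and labels."""
    series: list[SensorSeries] = []
    label_rows: list[pd.DataFrame] = []
    event_intervals: dict[str, list[tuple[pd.Timestamp, pd.Timestamp]]] = {
        "door": [], "person_1": [], "person_2": [], "person_3": []
    }
    person_cycle = 0

    # event logs derive from door/occupancy anomalies, independent of sensors
    for ev in cfg.anomalies:
        end = ev.start + pd.Timedelta(minutes=ev.duration_min)
        if ev.kind == "door_bump":
            event_intervals["door"].append((ev.start, end))
        elif ev.kind == "occupancy_bump":
            channel = f"person_{person_cycle % 3 + 1}"
            person_cycle += 1
            event_intervals[channel].append((ev.start, end))

    events = []
    for channel, intervals in event_intervals.items():
        intervals = sorted(intervals)
        ts, states = [], []
        for s, e in intervals:
            ts.extend([s, e])
            states.extend([1, 0])
        events.append(EventLog.from_raw(channel, pd.DatetimeIndex(ts), states))

    for ti, trial in enumerate(cfg.trials):
        grid = minute_grid(*trial.window)
        nominal_sp = _setpoint_profile(trial, grid)
        for si, sensor in enumerate(cfg.sensors):
            rng = np.random.default_rng([cfg.seed, ti, si])
            sp = nominal_sp.copy()
            labelled = np.zeros((len(grid),), dtype=object)

            def mark(lo, hi, kind):
                for i in range(lo, hi):
                    labelled[i] = kind if not labelled[i] else labelled[i]

            # ac_delay rewrites the setpoint schedule before the lag filter
            for ev in cfg.anomalies:
                if ev.kind == "ac_delay" and _affects(ev, sensor.sensor_id):
                    lo, hi = _block_slice(grid, ev.start, ev.duration_min)
                    shift = int(round(ev.magnitude))
                    delayed = np.roll(nominal_sp, shift)
                    changed = np.flatnonzero(delayed[lo:hi] != sp[lo:hi])
                    sp[lo:hi] = delayed[lo:hi]
                    mark_idx = changed + lo
                    for i in mark_idx:
                        labelled[i] = labelled[i] or "ac_delay"

            base = _lagged_response(sp, sensor.transition_lag_min, sp[0])
            values = base + sensor.bias
            if sensor.noise_sd > 0:
                values = values + rng.normal(0.0, sensor.noise_sd, len(grid))
            missing = np.zeros(len(grid), dtype=bool)

            for ev in cfg.anomalies:
                if not _affects(ev, sensor.sensor_id):
                    continue
                lo, hi = _block_slice(grid, ev.start, ev.duration_min)
                if lo >= hi:
                    continue
                if ev.kind in ("door_bump", "occupancy_bump", "power_surge_spike"):
                    values[lo:hi] += ev.magnitude
                    mark(lo, hi, ev.kind)
                elif ev.kind == "sensor_drift":
                    ramp = np.linspace(0.0, ev.magnitude, hi - lo)
                    values[lo:hi] += ramp
                    mark(lo, hi, ev.kind)
                elif ev.kind == "power_outage":
                    missing[lo:hi] = True
                    mark(lo, hi, ev.kind)

            for blk in cfg.missing_blocks:
                if not _affects(blk, sensor.sensor_id):
                    continue
                lo, hi = _block_slice(grid, blk.start, blk.duration_min)
                missing[lo:hi] = True

            # a slot missing on every day for this sensor will need
            # interpolation downstream; warn so tests can assert on it
            slot = (grid.hour * 60 + grid.minute).to_numpy()
            n_days = len(grid) // 1440
            if n_days > 0 and missing.any():
                slot_missing = np.bincount(slot[missing], minlength=1440)
                if (slot_missing >= n_days).any():
                    warnings.warn(
                        f"{sensor.sensor_id}/{trial.trial_id}: some hh:mm slots "
                        "are missing on every day; surrogate will interpolate",
                        stacklevel=2,
                    )

            values[missing] = np.nan
            series.append(
                SensorSeries(
                    sensor.sensor_id, trial.trial_id, grid, values, missing
                )
            )
            anomalous = np.flatnonzero(labelled != 0)
            if len(anomalous):
                label_rows.append(
                    pd.DataFrame(
                        {
                            "timestamp": grid[anomalous],
                            "sensor_id": sensor.sensor_id,
                            "trial_id": trial.trial_id,
                            "kind": [labelled[i] for i in anomalous],
                        }
                    )
                )

    labels = (
        pd.concat(label_rows, ignore_index=True)
        if label_rows
        else pd.DataFrame(columns=["timestamp", "sensor_id", "trial_id", "kind"])
    )
    return SimResult(series=series, events=events, labels=labels)


def simulate_raw(
    cfg: SimConfig, trial_index: int = 0, sensor_index: int = 0,
    cadence_s: int = 10,
) -> RawReadings:
    """High-cadence raw readings (noise + bias, no anomalies) for one
    sensor/trial; used to exercise minute averaging."""
    trial = cfg.trials[trial_index]
    sensor = cfg.sensors[sensor_index]
    start, end = trial.window
    ts = pd.date_range(start, end, freq=f"{cadence_s}s", inclusive="left")
    minute_grid_ = minute_grid(start, end)
    sp = _setpoint_profile(trial, minute_grid_)
    per_min = 60 // cadence_s
    base = np.repeat(_lagged_response(sp, sensor.transition_lag_min, sp[0]), per_min)
    rng = np.random.default_rng([cfg.seed, trial_index, sensor_index, cadence_s])
    values = base + sensor.bias
    if sensor.noise_sd > 0:
        values = values + rng.normal(0.0, sensor.noise_sd, len(ts))
    return RawReadings(sensor.sensor_id, ts, values)


@dataclass
class DetectionMetrics:
    recall_by_kind: dict[str, float]
    recall_overall: float  # NaN when no anomalies planted
    false_flag_rate: float
    n_anomalous: int
    n_clean: int


def labels_to_truth(labels: pd.DataFrame, outlier_rows: pd.DataFrame) -> DetectionMetrics:
    """Score flagged minutes against the planted-anomaly label table.

    `outlier_rows` needs columns timestamp, sensor_id, is_outlier (one row
    per scored minute).  Minutes absent from the label table count as clean.
    """
    key_cols = ["timestamp", "sensor_id"]
    lab = labels.drop_duplicates(subset=key_cols) if len(labels) else labels
    merged = outlier_rows.merge(
        lab[key_cols + ["kind"]] if len(lab) else pd.DataFrame(columns=key_cols + ["kind"]),
        on=key_cols, how="left",
    )
    is_anom = merged["kind"].notna()
    n_anom = int(is_anom.sum())
    n_clean = int((~is_anom).sum())
    recall_by_kind: dict[str, float] = {}
    for kind, grp in merged[is_anom].groupby("kind"):
        recall_by_kind[str(kind)] = float(grp["is_outlier"].mean())
    recall_overall = (
        float(merged.loc[is_anom, "is_outlier"].mean()) if n_anom else float("nan")
    )
    false_rate = (
        float(merged.loc[~is_anom, "is_outlier"].mean()) if n_clean else float("nan")
    )
    return DetectionMetrics(
        recall_by_kind=recall_by_kind,
        recall_overall=recall_overall,
        false_flag_rate=false_rate,
        n_anomalous=n_anom,
        n_clean=n_clean,
    )
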