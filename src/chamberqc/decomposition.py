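"""Median diurnal surrogate profiles and additive decomposition.

Two routes to residuals are provided:

* the *alternative* route — subtract the tiled 1440-slot median diurnal
  profile (the surrogate) from the gap-filled (coalesced) series; and
* the *standard additive* route — classical trend (centered moving average)
  plus seasonal-figure decomposition, kept as a comparator.

The surrogate is always built from the raw, pre-coalescing series so that
imputed values never feed back into the medians.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .timeseries import SensorSeries

__all__ = [
    "SLOTS_PER_DAY",
    "SurrogateProfile",
    "DecompositionResult",
    "build_surrogate",
    "coalesce",
    "alt_decompose",
    "standard_additive_decompose",
    "decomposition_frame",
]

SLOTS_PER_DAY = 1440


@dataclass
class SurrogateProfile:
    """Per-(hh:mm) median values for one sensor and trial.

    ``slots[i]`` is the median of all non-missing observations whose
    time-of-day equals slot ``i`` (i = hour*60 + minute) across the trial.
    Slots with zero support are filled by circular linear interpolation and
    recorded in ``interpolated_slots``.
    """

    sensor_id: str
    trial_id: str
    slots: np.ndarray
    support_counts: np.ndarray
    interpolated_slots: np.ndarray

    def __post_init__(self) -> None:
        self.slots = np.asarray(self.slots, dtype=float)
        self.support_counts = np.asarray(self.support_counts, dtype=int)
        self.interpolated_slots = np.asarray(self.interpolated_slots, dtype=int)
        if self.slots.shape != (SLOTS_PER_DAY,):
            raise ValueError("surrogate must have exactly 1440 slots")
        if not np.all(np.isfinite(self.slots)):
            raise ValueError("surrogate slots must all be finite")
        if (self.support_counts < 0).any():
            raise ValueError("support counts must be non-negative")

    def tiled(self, series: SensorSeries) -> np.ndarray:
        """Surrogate value at each grid minute of `series`."""
        return self.slots[series.slot_of_day()]


@dataclass
class DecompositionResult:
    """Additive split of a coalesced series into components.

    For the alternative method ``trend`` is NaN everywhere and
    ``coalesced = seasonal + residual`` exactly.  For the standard method
    ``coalesced = trend + seasonal + residual`` wherever the trend is
    defined (it is NaN within half a period of either edge).
    """

    method: str
    coalesced: SensorSeries
    seasonal: np.ndarray
    trend: np.ndarray
    residuals: np.ndarray
    filled_mask: np.ndarray

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return self.coalesced.timestamps


def _circular_interpolate(slots: np.ndarray, have: np.ndarray) -> np.ndarray:
    """Fill unsupported slots by linear interpolation on the hh:mm circle."""
    if have.all():
        return slots
    if not have.any():
        raise ValueError("no surrogate support")
    n = len(slots)
    out = slots.copy()
    idx = np.arange(n)
    sup = idx[have]
    for i in idx[~have]:
        # nearest supported slot on each side, wrapping at midnight
        after = sup[sup > i]
        before = sup[sup < i]
        nxt = after[0] if len(after) else sup[0] + n
        prv = before[-1] if len(before) else sup[-1] - n
        w = (i - prv) / (nxt - prv)
        out[i] = (1 - w) * slots[prv % n] + w * slots[nxt % n]
    return out


def build_surrogate(series: SensorSeries) -> SurrogateProfile:
    """Median of non-missing values at each hh:mm slot across the trial."""
    if len(series) < SLOTS_PER_DAY:
        raise ValueError("series must span at least one full day")
    if series.missing_mask.all():
        raise ValueError("no surrogate support")
    slot = series.slot_of_day()
    ok = ~series.missing_mask
    df = pd.DataFrame({"slot": slot[ok], "value": series.values[ok]})
    med = df.groupby("slot")["value"].median()
    cnt = df.groupby("slot")["value"].size()
    slots = np.full(SLOTS_PER_DAY, np.nan)
    counts = np.zeros(SLOTS_PER_DAY, dtype=int)
    slots[med.index.to_numpy()] = med.to_numpy()
    counts[cnt.index.to_numpy()] = cnt.to_numpy()
    have = counts > 0
    slots = _circular_interpolate(slots, have)
    return SurrogateProfile(
        series.sensor_id,
        series.trial_id,
        slots,
        counts,
        np.flatnonzero(~have),
    )


def coalesce(series: SensorSeries, surrogate: SurrogateProfile) -> DecompositionResult:
    """Replace missing minutes with the surrogate value at their hh:mm slot.

    Returns a partial result: ``coalesced`` and ``filled_mask`` are set;
    seasonal/trend/residual are NaN until a decomposition is applied.
    """
    if (surrogate.sensor_id, surrogate.trial_id) != (series.sensor_id, series.trial_id):
        raise ValueError("surrogate was built from a different sensor/trial")
    tiled = surrogate.tiled(series)
    values = np.where(series.missing_mask, tiled, series.values)
    coalesced = SensorSeries(
        series.sensor_id,
        series.trial_id,
        series.timestamps,
        values,
        np.zeros(len(series), dtype=bool),
    )
    n = len(series)
    nan = np.full(n, np.nan)
    return DecompositionResult(
        method="coalesced_only",
        coalesced=coalesced,
        seasonal=nan.copy(),
        trend=nan.copy(),
        residuals=nan.copy(),
        filled_mask=series.missing_mask.copy(),
    )


def alt_decompose(
    coalesced: DecompositionResult, surrogate: SurrogateProfile
) -> DecompositionResult:
    """De-seasonalize by subtracting the tiled surrogate from the coalesced
    series; the additive identity holds exactly and filled minutes have
    residual exactly zero."""
    series = coalesced.coalesced
    seasonal = surrogate.tiled(series)
    residuals = series.values - seasonal
    # imputed points equal the surrogate by construction: force exact zero
    residuals[coalesced.filled_mask] = 0.0
    return DecompositionResult(
        method="alternative",
        coalesced=series,
        seasonal=seasonal,
        trend=np.full(len(series), np.nan),
        residuals=residuals,
        filled_mask=coalesced.filled_mask.copy(),
    )


def _centered_moving_average(x: np.ndarray, period: int) -> np.ndarray:
    """Classical trend filter; split end-weights when the period is even."""
    if period % 2 == 0:
        w = np.full(period + 1, 1.0 / period)
        w[0] = w[-1] = 0.5 / period
    else:
        w = np.full(period, 1.0 / period)
    half = len(w) // 2
    trend = np.full(len(x), np.nan)
    conv = np.convolve(x, w[::-1], mode="valid")
    trend[half: half + len(conv)] = conv
    return trend


def standard_additive_decompose(
    coalesced: DecompositionResult, period: int = SLOTS_PER_DAY
) -> DecompositionResult:
    """Classical additive decomposition x = trend + seasonal + residual.

    Trend is the centered moving average over one period; the seasonal
    figure is the per-slot mean of the detrended series, centered to zero
    mean over one period, then tiled.  Trend and residual are undefined
    within period/2 of either edge.
    """
    series = coalesced.coalesced
    x = series.values
    if len(x) < 2 * period:
        raise ValueError("series must span at least two periods")
    trend = _centered_moving_average(x, period)
    detrended = x - trend
    phase = np.arange(len(x)) % period
    figure = np.full(period, np.nan)
    for p in range(period):
        vals = detrended[phase == p]
        vals = vals[~np.isnan(vals)]
        figure[p] = vals.mean() if len(vals) else np.nan
    figure -= np.nanmean(figure)
    seasonal = figure[phase]
    residuals = x - trend - seasonal
    return DecompositionResult(
        method="standard_additive",
        coalesced=series,
        seasonal=seasonal,
        trend=trend,
        residuals=residuals,
        filled_mask=coalesced.filled_mask.copy(),
    )


def decomposition_frame(result: DecompositionResult) -> pd.DataFrame:
    """Tidy frame: timestamp,sensor_id,trial_id,coalesced,seasonal,trend,residual,filled."""
    s = result.coalesced
    return pd.DataFrame(
        {
            "timestamp": s.timestamps,
            "sensor_id": s.sensor_id,
            "trial_id": s.trial_id,
            "coalesced": s.values,
            "seasonal": result.seasonal,
            "trend": result.trend,
            "residual": result.residuals,
            "filled": result.filled_mask,
        }
    )
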