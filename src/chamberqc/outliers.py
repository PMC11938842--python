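"""Residual z-scoring and outlier labelling.

Residuals are standardized within each (sensor, trial, method) group using
the sample mean and sample standard deviation (n-1 denominator), and flagged
when |z| exceeds the two-sided normal critical value for the configured
significance level (default alpha = 0.001, threshold ~= 3.29).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .decomposition import DecompositionResult
from .timeseries import SensorSeries

__all__ = [
    "OutlierConfig",
    "OutlierTable",
    "critical_z",
    "zscore_outliers",
    "summarize_residuals",
    "summarize_raw",
]


@dataclass(frozen=True)
class OutlierConfig:
    """Flagging rule: two-sided level `alpha`; strict => |z| > threshold,
    otherwise |z| >= threshold."""

    alpha: float = 0.001
    strict: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")


def critical_z(alpha: float) -> float:
    """Two-sided standard-normal critical value: the (1 - alpha/2) quantile."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    return float(stats.norm.ppf(1.0 - alpha / 2.0))


@dataclass
class OutlierTable:
    """Per-minute residual z-scores and flags for one sensor/trial/method."""

    sensor_id: str
    trial_id: str
    method: str
    rows: pd.DataFrame  # timestamp, residual, z, is_outlier, filled
    residual_mean: float
    residual_sd: float
    threshold: float
    alpha: float
    strict: bool

    @property
    def n(self) -> int:
        return len(self.rows)

    @property
    def outlier_count(self) -> int:
        return int(self.rows["is_outlier"].sum())

    def outliers(self) -> pd.DataFrame:
        return self.rows[self.rows["is_outlier"]]


def zscore_outliers(
    result: DecompositionResult, cfg: OutlierConfig = OutlierConfig()
) -> OutlierTable:
    """Standardize residuals and flag outliers.

    Rows where the residual is undefined (edge minutes of the standard
    method) are dropped before computing the group mean/sd.  Raises on a
    degenerate group (sd == 0) or fewer than two residuals.
    """
    series = result.coalesced
    defined = ~np.isnan(result.residuals)
    r = result.residuals[defined]
    if len(r) < 2:
        raise ValueError("need at least two defined residuals")
    mean = float(r.mean())
    sd = float(r.std(ddof=1))
    if sd == 0.0:
        raise ValueError(
            f"degenerate residuals (sd = 0) for {series.sensor_id}/{series.trial_id}"
        )
    threshold = critical_z(cfg.alpha)
    z = (r - mean) / sd
    flagged = np.abs(z) > threshold if cfg.strict else np.abs(z) >= threshold
    rows = pd.DataFrame(
        {
            "timestamp": series.timestamps[defined],
            "residual": r,
            "z": z,
            "is_outlier": flagged,
            "filled": result.filled_mask[defined],
        }
    )
    return OutlierTable(
        sensor_id=series.sensor_id,
        trial_id=series.trial_id,
        method=result.method,
        rows=rows,
        residual_mean=mean,
        residual_sd=sd,
        threshold=threshold,
        alpha=cfg.alpha,
        strict=cfg.strict,
    )


def summarize_residuals(tables: list[OutlierTable]) -> pd.DataFrame:
    """Per-(sensor, trial, method) residual mean, sd and outlier count."""
    recs = [
        {
            "sensor_id": t.sensor_id,
            "trial_id": t.trial_id,
            "method": t.method,
            "mean": t.residual_mean,
            "sd": t.residual_sd,
            "outlier_count": t.outlier_count,
            "n": t.n,
        }
        for t in tables
    ]
    return pd.DataFrame.from_records(
        recs, columns=["sensor_id", "trial_id", "method", "mean", "sd",
                       "outlier_count", "n"]
    )


def summarize_raw(series_list: list[SensorSeries]) -> pd.DataFrame:
    """Raw-data descriptive statistics per sensor/trial, including NA count."""
    recs = []
    for s in series_list:
        v = s.values[~s.missing_mask]
        recs.append(
            {
                "sensor_id": s.sensor_id,
                "trial_id": s.trial_id,
                "mean": float(v.mean()) if v.size else np.nan,
                "median": float(np.median(v)) if v.size else np.nan,
                "sd": float(v.std(ddof=1)) if v.size > 1 else np.nan,
                "min": float(v.min()) if v.size else np.nan,
                "max": float(v.max()) if v.size else np.nan,
                "na_count": s.n_missing,
                "n": len(s),
            }
        )
    return pd.DataFrame.from_records(
        recs, columns=["sensor_id", "trial_id", "mean", "median", "sd",
                       "min", "max", "na_count", "n"]
    )
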