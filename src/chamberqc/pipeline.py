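"""End-to-end pipeline: sensor/event CSVs in, report bundle out.

Stages: grid alignment -> surrogate -> coalesce -> both decompositions ->
z-score outliers -> residual/raw summaries -> |z| distribution fitting ->
cumulative Agr.Ops -> stability regression.  All tabular outputs are CSV;
a JSON manifest records the config hash, seed and package version so a rerun
with the same inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .agrops import AgrOpsWeights, cumulative_agr_ops, events_to_minutes
from .decomposition import (
    alt_decompose,
    build_surrogate,
    coalesce,
    decomposition_frame,
    standard_additive_decompose,
)
from .distfit import distfit_frame, fit_distributions
from .outliers import OutlierConfig, summarize_raw, summarize_residuals, zscore_outliers
from .regression import fit_stability_glm, regression_frame
from .timeseries import TrialConfig, read_event_log, read_sensor_log

logger = logging.getLogger("chamberqc")

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    sensor_csv: str
    event_csv: str | None
    out_dir: str
    trials: list[TrialConfig]
    alpha: float = 0.001
    strict: bool = True
    fit_method: str = "mle"
    person_weight: float = 1.0
    door_weight: float = 0.0
    exclude_sensors_from_fit: tuple[str, ...] = ()
    regression_family: str = "lognormal"
    seed: int = 0
    plots: bool = False

    def to_dict(self) -> dict:
        return {
            "sensor_csv": str(self.sensor_csv),
            "event_csv": str(self.event_csv) if self.event_csv else None,
            "out_dir": str(self.out_dir),
            "alpha": self.alpha,
            "strict": self.strict,
            "fit_method": self.fit_method,
            "person_weight": self.person_weight,
            "door_weight": self.door_weight,
            "exclude_sensors_from_fit": list(self.exclude_sensors_from_fit),
            "regression_family": self.regression_family,
            "seed": self.seed,
            "plots": self.plots,
            "trials": [
                {
                    "trial_id": t.trial_id,
                    "day_setpoint": t.day_setpoint,
                    "night_setpoint": t.night_setpoint,
                    "day_hours": t.day_hours,
                    "night_hours": t.night_hours,
                    "window": [str(t.window[0]), str(t.window[1])],
                    "analysis_window": [
                        str(t.analysis_window[0]), str(t.analysis_window[1])
                    ],
                    "day_start": t.day_start,
                }
                for t in self.trials
            ],
        }

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    """Load a pipeline configuration from YAML."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    trials = [
        TrialConfig(
            trial_id=t["trial_id"],
            day_setpoint=float(t["day_setpoint"]),
            night_setpoint=float(t["night_setpoint"]),
            day_hours=float(t.get("day_hours", 16.5)),
            night_hours=float(t.get("night_hours", 7.5)),
            window=tuple(t["window"]),
            analysis_window=tuple(t["analysis_window"]) if "analysis_window" in t else None,
            day_start=t.get("day_start", "06:00"),
        )
        for t in raw["trials"]
    ]
    return PipelineConfig(
        sensor_csv=raw["sensor_csv"],
        event_csv=raw.get("event_csv"),
        out_dir=raw["out_dir"],
        trials=trials,
        alpha=float(raw.get("alpha", 0.001)),
        strict=bool(raw.get("strict", True)),
        fit_method=raw.get("fit_method", "mle"),
        person_weight=float(raw.get("person_weight", 1.0)),
        door_weight=float(raw.get("door_weight", 0.0)),
        exclude_sensors_from_fit=tuple(raw.get("exclude_sensors_from_fit", ())),
        regression_family=raw.get("regression_family", "lognormal"),
        seed=int(raw.get("seed", 0)),
        plots=bool(raw.get("plots", False)),
    )


def _write_csv(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage and write the report bundle to ``cfg.out_dir``.

    Returns a manifest dict (also written as ``manifest.json``).  Degenerate
    residual groups (sd == 0, e.g. noiseless input) are reported with zero
    outliers rather than aborting the run; stage-level errors propagate with
    the stage name and leave a FAILED marker in the bundle.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = cfg.config_hash()
    stage = "read_inputs"
    try:
        all_series = read_sensor_log(cfg.sensor_csv)
        logs = read_event_log(cfg.event_csv) if cfg.event_csv else None

        stage = "decompose"
        tables = []
        raw_slices = []
        decomp_frames = []
        degenerate: list[str] = []
        by_trial_outliers: list[pd.DataFrame] = []
        cfg_out = OutlierConfig(alpha=cfg.alpha, strict=cfg.strict)
        for trial in cfg.trials:
            for s in all_series:
                try:
                    sl = s.slice_window(*trial.analysis_window)
                except ValueError:
                    continue  # sensor does not cover this trial
                sl.trial_id = trial.trial_id
                raw_slices.append(sl)
                surrogate = build_surrogate(sl)
                part = coalesce(sl, surrogate)
                alt = alt_decompose(part, surrogate)
                std = standard_additive_decompose(part)
                decomp_frames.append(decomposition_frame(alt))
                for result in (alt, std):
                    try:
                        t = zscore_outliers(result, cfg_out)
                    except ValueError as exc:
                        if "degenerate" in str(exc):
                            degenerate.append(
                                f"{sl.sensor_id}/{trial.trial_id}/{result.method}"
                            )
                            continue
                        raise
                    tables.append(t)
                    if result.method == "alternative":
                        rows = t.rows.assign(
                            sensor_id=t.sensor_id, trial_id=t.trial_id
                        )
                        by_trial_outliers.append(rows)

        stage = "summaries"
        summary = summarize_residuals(tables)
        if degenerate:
            extra = pd.DataFrame(
                [
                    {
                        "sensor_id": g.split("/")[0],
                        "trial_id": g.split("/")[1],
                        "method": g.split("/")[2],
                        "mean": 0.0, "sd": 0.0, "outlier_count": 0, "n": 0,
                    }
                    for g in degenerate
                ]
            )
            summary = pd.concat([summary, extra], ignore_index=True)
        summary = summary.sort_values(["sensor_id", "trial_id", "method"]).reset_index(drop=True)
        raw_summary = summarize_raw(raw_slices)

        _write_csv(raw_summary, out / "raw_summary.csv", chash)
        _write_csv(summary, out / "summary.csv", chash)
        all_decomp = pd.concat(decomp_frames, ignore_index=True) if decomp_frames else pd.DataFrame()
        _write_csv(all_decomp, out / "decomposition.csv", chash)

        outlier_rows = (
            pd.concat(by_trial_outliers, ignore_index=True)
            if by_trial_outliers else pd.DataFrame(
                columns=["timestamp", "residual", "z", "is_outlier", "filled",
                         "sensor_id", "trial_id"])
        )
        meta_cols = outlier_rows.assign(
            alpha=cfg.alpha,
            threshold=tables[0].threshold if tables else np.nan,
        )
        _write_csv(meta_cols, out / "outliers.csv", chash)

        stage = "fit_distributions"
        pool = outlier_rows[
            outlier_rows["is_outlier"]
            & ~outlier_rows["sensor_id"].isin(cfg.exclude_sensors_from_fit)
        ]
        distfit_df = pd.DataFrame()
        if len(pool) >= 10:
            fits = fit_distributions(np.abs(pool["z"].to_numpy()), method=cfg.fit_method)
            distfit_df = distfit_frame(fits)
        else:
            logger.warning("too few outliers (%d) for distribution fitting", len(pool))
        _write_csv(distfit_df, out / "distfit.csv", chash)

        stage = "agr_ops"
        agrops_frames = []
        regression_df = pd.DataFrame()
        if logs is not None:
            weights = AgrOpsWeights(person=cfg.person_weight, door=cfg.door_weight)
            reg_rows = []
            for trial in cfg.trials:
                mins = events_to_minutes(logs, trial.analysis_window)
                ops = cumulative_agr_ops(mins, weights)
                agrops_frames.append(ops.frame().assign(trial_id=trial.trial_id))
                cum = pd.Series(ops.cumulative, index=ops.timestamps)
                trial_out = pool[pool["trial_id"] == trial.trial_id]
                if len(trial_out):
                    joined = trial_out.assign(
                        agr_ops=cum.reindex(trial_out["timestamp"]).to_numpy(),
                        abs_z=np.abs(trial_out["z"].to_numpy()),
                    )
                    reg_rows.append(joined)
            agrops_df = (
                pd.concat(agrops_frames, ignore_index=True)
                if agrops_frames else pd.DataFrame()
            )
            _write_csv(agrops_df, out / "agrops.csv", chash)

            stage = "stability_regression"
            notes = []
            if reg_rows:
                reg_input = pd.concat(reg_rows, ignore_index=True)
                try:
                    fits = fit_stability_glm(
                        reg_input[["abs_z", "agr_ops", "sensor_id", "trial_id"]],
                        per_trial=True,
                        family=cfg.regression_family,
                    )
                    parts = []
                    for label, res in fits.items():
                        frame = regression_frame(res).assign(fit=label)
                        parts.append(frame)
                        notes.extend(f"{label}: {n}" for n in res.notes)
                    regression_df = pd.concat(parts, ignore_index=True)
                except ValueError as exc:
                    notes.append(f"regression skipped: {exc}")
            else:
                notes.append("regression skipped: no outlier rows")
            _write_csv(regression_df, out / "regression.csv", chash)
        else:
            notes = ["no event log supplied; Agr.Ops and regression skipped"]

        stage = "manifest"
        manifest = {
            "config_hash": chash,
            "seed": cfg.seed,
            "version": __version__,
            "alpha": cfg.alpha,
            "threshold": float(tables[0].threshold) if tables else None,
            "n_groups": int(len(summary)),
            "degenerate_groups": degenerate,
            "notes": notes,
            "outputs": sorted(p.name for p in out.glob("*.csv")),
            "config": cfg.to_dict(),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return manifest
    except Exception as exc:
        (out / "FAILED").write_text(f"stage={stage}: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
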