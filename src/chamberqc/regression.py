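"""Stability regression of outlier severity against cumulative operations.

The "log-normal" regression is realized as a Gaussian GLM with identity link
on log(|z|):  log|z| ~ Agr_Ops * sensor, with treatment coding and the
alphabetically first sensor as baseline.  A Gamma/log-link alternative is
available behind the ``family`` flag.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = ["RegressionResult", "fit_stability_glm", "regression_frame"]

REQUIRED_COLUMNS = ("abs_z", "agr_ops", "sensor_id")


@dataclass
class RegressionResult:
    coefficients: pd.DataFrame  # coefficient, estimate, std_error, t_value, p_value
    family: str
    formula: str
    n: int
    baseline_sensor: str | None
    notes: list[str] = field(default_factory=list)

    def coef(self, name: str) -> float:
        row = self.coefficients.loc[self.coefficients["coefficient"] == name]
        if row.empty:
            raise KeyError(name)
        return float(row["estimate"].iloc[0])

    def row(self, name: str) -> pd.Series:
        sel = self.coefficients.loc[self.coefficients["coefficient"] == name]
        if sel.empty:
            raise KeyError(name)
        return sel.iloc[0]


def _pretty_names(names: list[str]) -> list[str]:
    out = []
    for name in names:
        name = name.replace("Intercept", "Intercept")
        name = re.sub(r"C\(sensor_id[^)]*\)\[T\.([^\]]+)\]", r"\1", name)
        name = name.replace("agr_ops", "Agr_Ops")
        out.append(name)
    return out


def _fit_one(df: pd.DataFrame, family: str, min_cell: int) -> RegressionResult:
    notes: list[str] = []
    sensors = sorted(df["sensor_id"].unique())
    baseline = sensors[0] if len(sensors) > 1 else None
    with_interaction = len(sensors) > 1
    if with_interaction and min_cell > 0:
        cell_counts = df.groupby("sensor_id").size()
        if (cell_counts < min_cell).any():
            with_interaction = False
            notes.append(
                "interaction dropped: sensor cell below "
                f"{min_cell} outliers ({dict(cell_counts[cell_counts < min_cell])})"
            )
    if len(sensors) > 1:
        formula_rhs = (
            "agr_ops * C(sensor_id)" if with_interaction
            else "agr_ops + C(sensor_id)"
        )
    else:
        formula_rhs = "agr_ops"
    if df["agr_ops"].nunique() < 2:
        raise ValueError("need at least two distinct cumulative Agr.Ops values")

    if family == "lognormal":
        formula = f"log_abs_z ~ {formula_rhs}"
        model = smf.ols(formula, data=df.assign(log_abs_z=np.log(df["abs_z"])))
        fit = model.fit()
        est, se, tval, pval = fit.params, fit.bse, fit.tvalues, fit.pvalues
    elif family == "gamma_log":
        formula = f"abs_z ~ {formula_rhs}"
        model = smf.glm(formula, data=df,
                        family=sm.families.Gamma(link=sm.families.links.Log()))
        fit = model.fit()
        est, se, tval, pval = fit.params, fit.bse, fit.tvalues, fit.pvalues
    else:
        raise ValueError(f"unknown family {family!r}")

    coefs = pd.DataFrame(
        {
            "coefficient": _pretty_names(list(est.index)),
            "estimate": est.to_numpy(),
            "std_error": se.to_numpy(),
            "t_value": tval.to_numpy(),
            "p_value": pval.to_numpy(),
        }
    )
    return RegressionResult(
        coefficients=coefs,
        family=family,
        formula=formula,
        n=len(df),
        baseline_sensor=baseline,
        notes=notes,
    )


def fit_stability_glm(
    data: pd.DataFrame,
    per_trial: bool = False,
    family: str = "lognormal",
    min_cell: int = 10,
) -> RegressionResult | dict[str, RegressionResult]:
    """Fit log|z| ~ Agr_Ops x sensor on outlier rows only.

    `data` needs columns abs_z (> 0), agr_ops (cumulative covariate at the
    outlier's minute), sensor_id and, when ``per_trial``, trial_id.  With
    ``per_trial=True`` returns one fit per trial plus a ``"combined"`` fit.
    The sensor interaction is dropped with a note when any sensor cell has
    fewer than `min_cell` outliers.
    """
    for col in REQUIRED_COLUMNS:
        if col not in data.columns:
            raise ValueError(f"missing required column {col!r}")
    if (data["abs_z"] <= 0).any():
        raise ValueError("abs_z must be strictly positive")
    if len(data) < 3:
        raise ValueError("too few outlier rows to fit")
    if not per_trial:
        return _fit_one(data, family, min_cell)
    if "trial_id" not in data.columns:
        raise ValueError("per_trial fits require a trial_id column")
    out: dict[str, RegressionResult] = {}
    for trial_id, grp in data.groupby("trial_id", sort=True):
        try:
            out[str(trial_id)] = _fit_one(grp, family, min_cell)
        except ValueError as exc:
            out[str(trial_id)] = RegressionResult(
                coefficients=pd.DataFrame(
                    columns=["coefficient", "estimate", "std_error",
                             "t_value", "p_value"]
                ),
                family=family, formula="", n=len(grp), baseline_sensor=None,
                notes=[f"fit skipped: {exc}"],
            )
    out["combined"] = _fit_one(data, family, min_cell)
    return out


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.1:
        return "."
    return ""


def regression_frame(result: RegressionResult) -> pd.DataFrame:
    """Coefficient table with significance stars."""
    df = result.coefficients.copy()
    df["significance"] = [_stars(p) for p in df["p_value"]]
    return df
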