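"""Candidate-distribution fitting for outlier |z| magnitudes.

Six two-parameter families are fitted (normal, lognormal, gamma, weibull,
logistic, cauchy) and ranked by AIC.  Default estimation is maximum
likelihood; maximum-goodness-of-fit estimation minimizing the Cramér-von
Mises distance is available as ``method="mge_cvm"``.  Parameter names follow
the conventional shape/rate/scale naming for each family.

Note: the |z| inputs are threshold-truncated by construction; the candidate
families are nevertheless fitted unconditionally (no truncation correction),
matching the comparison these rankings support.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = ["DistFitResult", "fit_distributions", "DISTRIBUTIONS"]

DISTRIBUTIONS = ("normal", "lognormal", "gamma", "weibull", "logistic", "cauchy")

_POSITIVE_ONLY = {"lognormal", "gamma", "weibull"}


@dataclass
class DistFitResult:
    distribution: str
    params: dict[str, float]
    loglik: float
    aic: float
    bic: float
    n: int
    fit_method: str
    ok: bool = True
    message: str = ""

    @property
    def k(self) -> int:
        return len(self.params)


def _frozen(name: str, params: dict[str, float]):
    if name == "normal":
        return stats.norm(loc=params["mean"], scale=params["sd"])
    if name == "lognormal":
        return stats.lognorm(s=params["sdlog"], scale=np.exp(params["meanlog"]))
    if name == "gamma":
        return stats.gamma(a=params["shape"], scale=1.0 / params["rate"])
    if name == "weibull":
        return stats.weibull_min(c=params["shape"], scale=params["scale"])
    if name == "logistic":
        return stats.logistic(loc=params["location"], scale=params["scale"])
    if name == "cauchy":
        return stats.cauchy(loc=params["location"], scale=params["scale"])
    raise ValueError(f"unknown distribution {name!r}")


def _mle(name: str, y: np.ndarray) -> dict[str, float]:
    if name == "normal":
        return {"mean": float(y.mean()), "sd": float(y.std(ddof=0))}
    if name == "lognormal":
        ly = np.log(y)
        return {"meanlog": float(ly.mean()), "sdlog": float(ly.std(ddof=0))}
    if name == "gamma":
        a, _, scale = stats.gamma.fit(y, floc=0)
        return {"shape": float(a), "rate": float(1.0 / scale)}
    if name == "weibull":
        c, _, scale = stats.weibull_min.fit(y, floc=0)
        return {"shape": float(c), "scale": float(scale)}
    if name == "logistic":
        loc, scale = stats.logistic.fit(y)
        return {"location": float(loc), "scale": float(scale)}
    if name == "cauchy":
        loc, scale = stats.cauchy.fit(y)
        return {"location": float(loc), "scale": float(scale)}
    raise ValueError(f"unknown distribution {name!r}")


def _cvm_distance(name: str, params: dict[str, float], y_sorted: np.ndarray) -> float:
    n = len(y_sorted)
    cdf = _frozen(name, params).cdf(y_sorted)
    i = np.arange(1, n + 1)
    return float(1.0 / (12.0 * n) + np.sum((cdf - (2 * i - 1) / (2.0 * n)) ** 2))


def _mge_cvm(name: str, y: np.ndarray) -> dict[str, float]:
    """Minimize the Cramér-von Mises distance, seeded at the MLE."""
    start = _mle(name, y)
    keys = list(start)
    y_sorted = np.sort(y)
    # scale/shape-like parameters are positive; meanlog and locations are not
    positive = [k in ("sd", "sdlog", "scale", "rate", "shape") for k in keys]

    def objective(theta):
        p = dict(zip(keys, theta))
        for k, must_pos in zip(keys, positive):
            if must_pos and p[k] <= 0:
                return np.inf
        with np.errstate(all="ignore"):
            d = _cvm_distance(name, p, y_sorted)
        return d if np.isfinite(d) else np.inf

    res = optimize.minimize(
        objective, np.array([start[k] for k in keys]), method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
    )
    if not res.success:
        raise RuntimeError(f"CvM optimizer did not converge: {res.message}")
    return dict(zip(keys, (float(v) for v in res.x)))


def fit_distributions(
    abs_z: np.ndarray, method: str = "mle"
) -> list[DistFitResult]:
    """Fit all candidate families to positive magnitudes and rank by AIC.

    Failed candidates (non-positive data for a log family, optimizer
    failure) are returned last with ``ok=False`` and a message.
    """
    if method not in ("mle", "mge_cvm"):
        raise ValueError(f"unknown method {method!r}")
    y = np.asarray(abs_z, dtype=float)
    y = y[~np.isnan(y)]
    if len(y) < 10:
        raise ValueError(f"need at least 10 values, got {len(y)}")
    has_nonpositive = bool((y <= 0).any())
    results: list[DistFitResult] = []
    for name in DISTRIBUTIONS:
        if has_nonpositive and name in _POSITIVE_ONLY:
            results.append(
                DistFitResult(name, {}, np.nan, np.nan, np.nan, len(y), method,
                              ok=False, message="non-positive data for log-family")
            )
            continue
        try:
            params = _mle(name, y) if method == "mle" else _mge_cvm(name, y)
            loglik = float(_frozen(name, params).logpdf(y).sum())
            if not np.isfinite(loglik):
                raise RuntimeError("non-finite log-likelihood at fitted parameters")
            k = len(params)
            aic = 2.0 * k - 2.0 * loglik
            bic = k * np.log(len(y)) - 2.0 * loglik
            results.append(
                DistFitResult(name, params, loglik, aic, bic, len(y), method)
            )
        except Exception as exc:  # noqa: BLE001 - candidate-level isolation
            results.append(
                DistFitResult(name, {}, np.nan, np.nan, np.nan, len(y), method,
                              ok=False, message=str(exc))
            )
    results.sort(key=lambda r: (not r.ok, r.aic if r.ok else np.inf))
    return results


def distfit_frame(results: list[DistFitResult]) -> pd.DataFrame:
    """Tabular layout: distribution, params, loglik, aic, bic, rank."""
    recs = []
    for rank, r in enumerate(results, start=1):
        recs.append(
            {
                "distribution": r.distribution,
                "params": "; ".join(f"{k}={v:.7g}" for k, v in r.params.items()),
                "loglik": r.loglik,
                "aic": r.aic,
                "bic": r.bic,
                "n": r.n,
                "fit_method": r.fit_method,
                "rank": rank if r.ok else np.nan,
                "ok": r.ok,
                "message": r.message,
            }
        )
    return pd.DataFrame.from_records(recs)
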