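"""Saturating (logistic) versus linear models of group size on local density.

If group size simply tracked the number of birds available at a site, the
relationship between the local population (unique individuals recorded at
a feeder in a sampling period) and the group sizes there would be linear.
Group-size regulation instead predicts saturation: a logistic curve

    y = K / (1 + exp(-(x - x0) / s))

whose upper asymptote K is the regulated maximum group size.  Both models
are fitted by least squares with a Gaussian likelihood and compared by
AIC; ``delta_aic = AIC_linear - AIC_logistic`` is positive when the
saturating model is better supported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .groups import GroupByIndividualMatrix

__all__ = [
    "local_population_table",
    "logistic_curve",
    "SaturationFit",
    "SaturationModel",
    "SaturationResults",
    "fit_saturation",
]


def local_population_table(matrix: GroupByIndividualMatrix) -> pd.DataFrame:
    """Per (feeder, sampling period): unique individuals and group sizes.

    Returns columns ``feeder_id, sampling_period, local_population,
    mean_group_size, max_group_size``; strata with no groups are absent.
    """
    rows = []
    for (feeder, period), idx in matrix.meta.groupby(
        ["feeder_id", "sampling_period"]
    ).indices.items():
        sub = matrix.incidence[np.asarray(idx)]
        sizes = sub.sum(axis=1)
        rows.append(
            (
                feeder,
                period,
                int(sub.any(axis=0).sum()),
                float(sizes.mean()),
                int(sizes.max()),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "feeder_id",
            "sampling_period",
            "local_population",
            "mean_group_size",
            "max_group_size",
        ],
    ).sort_values(["feeder_id", "sampling_period"], ignore_index=True)


def logistic_curve(x: np.ndarray, k: float, x0: float, s: float) -> np.ndarray:
    return k / (1.0 + np.exp(-(np.asarray(x, float) - x0) / s))


@dataclass
class SaturationFit:
    """One fitted model of group size against local population size."""

    model: str                      # "linear" | "logistic"
    params: dict[str, float]
    log_likelihood: float
    aic: float
    n_obs: int
    converged: bool = True
    message: str = ""

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        if self.model == "linear":
            return self.params["intercept"] + self.params["slope"] * x
        return logistic_curve(x, self.params["asymptote"], self.params["midpoint"], self.params["scale"])


def _gaussian_ll(residuals: np.ndarray) -> float:
    n = len(residuals)
    rss = float(residuals @ residuals)
    sigma2 = max(rss / n, 1e-12)
    return -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)


def _fit_linear(x: np.ndarray, y: np.ndarray) -> SaturationFit:
    slope, intercept = np.polyfit(x, y, 1)
    ll = _gaussian_ll(y - (intercept + slope * x))
    return SaturationFit(
        "linear",
        {"intercept": float(intercept), "slope": float(slope)},
        ll,
        2 * 3 - 2 * ll,   # intercept, slope, sigma
        len(x),
    )


def _fit_logistic(x: np.ndarray, y: np.ndarray) -> SaturationFit:
    sd_x = float(np.std(x)) or 1.0
    starts = [
        (float(np.max(y)) * 1.05, float(np.median(x)), sd_x / 2),
        (float(np.max(y)) * 1.5, float(np.mean(x)), sd_x),
        (float(np.max(y)) * 1.05, float(np.percentile(x, 25)), sd_x / 4),
    ]
    best: SaturationFit | None = None
    last_err = ""
    for k0, x00, s0 in starts:
        try:
            popt, _ = curve_fit(
                logistic_curve,
                x,
                y,
                p0=[k0, x00, s0],
                bounds=([1e-9, -np.inf, 1e-9], [np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
        except (RuntimeError, ValueError) as exc:
            last_err = str(exc)
            continue
        ll = _gaussian_ll(y - logistic_curve(x, *popt))
        fit = SaturationFit(
            "logistic",
            {"asymptote": float(popt[0]), "midpoint": float(popt[1]), "scale": float(popt[2])},
            ll,
            2 * 4 - 2 * ll,   # K, x0, s, sigma
            len(x),
        )
        if best is None or fit.aic < best.aic:
            best = fit
    if best is None:
        return SaturationFit(
            "logistic", {}, np.nan, np.nan, len(x), converged=False, message=last_err
        )
    return best


def fit_saturation(
    records: pd.DataFrame, response: str = "mean"
) -> tuple[SaturationFit, SaturationFit, float]:
    """Fit linear and logistic models of a group-size response on density.

    ``records`` is the frame from :func:`local_population_table` (or any
    frame with ``local_population`` and the response column).  Returns the
    two fits and ``delta_aic = AIC_linear - AIC_logistic`` (NaN when the
    logistic fit failed).
    """
    col = {"mean": "mean_group_size", "max": "max_group_size"}.get(response, response)
    x = records["local_population"].to_numpy(float)
    y = records[col].to_numpy(float)
    if len(x) < 5 or len(np.unique(x)) < 3:
        raise ValueError("need >= 5 records spanning >= 3 distinct population sizes")
    lin = _fit_linear(x, y)
    logi = _fit_logistic(x, y)
    delta = lin.aic - logi.aic if logi.converged else float("nan")
    return lin, logi, delta


def week_trend(matrix: GroupByIndividualMatrix, response: str = "mean") -> dict:
    """Descriptive fixed-effects check of a sampling-period trend in group size.

    Ordinary least squares of the group-size response on local population
    size plus sampling period.  This is *not* a mixed model (no location
    random effect); it only flags whether group size drifts over the season
    once local density is controlled for.
    """
    records = local_population_table(matrix)
    col = {"mean": "mean_group_size", "max": "max_group_size"}[response]
    x = np.column_stack(
        [
            np.ones(len(records)),
            records["local_population"].to_numpy(float),
            records["sampling_period"].to_numpy(float),
        ]
    )
    y = records[col].to_numpy(float)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    dof = max(len(y) - x.shape[1], 1)
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(x.T @ x)
    se = float(np.sqrt(cov[2, 2]))
    return {
        "period_slope": float(beta[2]),
        "period_slope_se": se,
        "t_value": float(beta[2] / se) if se > 0 else float("nan"),
        "n_obs": len(y),
    }


@dataclass
class SaturationResults:
    """Results of a linear-versus-logistic group-size comparison."""

    linear: SaturationFit
    logistic: SaturationFit
    delta_aic: float
    response: str
    records: pd.DataFrame = field(repr=False)

    @property
    def preferred(self) -> str:
        if not self.logistic.converged:
            return "linear"
        return "logistic" if self.delta_aic > 0 else "linear"

    def summary(self) -> str:
        lines = [
            f"Group size ~ local population size  (response: {self.response}, "
            f"n = {self.linear.n_obs})",
            "-" * 66,
            f"linear    intercept = {self.linear.params['intercept']:8.3f}   "
            f"slope = {self.linear.params['slope']:8.4f}   AIC = {self.linear.aic:9.2f}",
        ]
        if self.logistic.converged:
            p = self.logistic.params
            lines.append(
                f"logistic  asymptote K = {p['asymptote']:6.2f}   midpoint = {p['midpoint']:7.2f}"
                f"   scale = {p['scale']:6.2f}   AIC = {self.logistic.aic:9.2f}"
            )
            lines.append(
                f"delta AIC (linear - logistic) = {self.delta_aic:8.2f}"
                f"   preferred: {self.preferred}"
            )
        else:
            lines.append(f"logistic fit did not converge: {self.logistic.message}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "linear": {**self.linear.params, "aic": self.linear.aic},
            "logistic": {
                **self.logistic.params,
                "aic": self.logistic.aic,
                "converged": self.logistic.converged,
            },
            "delta_aic": self.delta_aic,
            "preferred": self.preferred,
        }


class SaturationModel:
    """Model object for the group-size saturation comparison.

    Construct from a record table (``from_records``) or directly from a
    group-by-individual matrix (``from_matrix``), then call :meth:`fit`.
    """

    def __init__(self, records: pd.DataFrame, response: str = "mean"):
        self.records = records
        self.response = response

    @classmethod
    def from_matrix(cls, matrix: GroupByIndividualMatrix, response: str = "mean"):
        return cls(local_population_table(matrix), response)

    @classmethod
    def from_records(cls, records: pd.DataFrame, response: str = "mean"):
        return cls(records, response)

    def fit(self) -> SaturationResults:
        lin, logi, delta = fit_saturation(self.records, self.response)
        return SaturationResults(lin, logi, delta, self.response, self.records)
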