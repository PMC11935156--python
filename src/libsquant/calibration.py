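"""Svalue-vs-concentration calibration, confidence band and inverse prediction.

The calibration line y = m·x + b is an ordinary least-squares fit of the
Svalue (counts/cm²) against reference concentrations (μg g⁻¹, e.g. from
ICP-MS on matched specimens).  From the fit come the method detection limits
in concentration units,

    LoD = 3.3·σ_fit / m,    LoQ = 10·σ_fit / m,

where σ_fit = √(SS_res/(n−2)) is the residual standard error, a mean-response
confidence band at a configurable level (70% by default), the σ_CC uncertainty
component (relative band half-width at the median design concentration), and
the inverse prediction x̂ = (y − b)/m for unknown specimens.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps


@dataclass(frozen=True)
class CalibrationPoint:
    sample_id: str
    concentration: float  # μg g⁻¹
    svalue: float  # counts/cm²
    group: str | None = None

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        if self.svalue < 0:
            raise ValueError("svalue must be >= 0")


@dataclass
class CalibrationModel:
    """Fitted line plus the design moments needed for bands and prediction."""

    m: float  # slope, counts/cm² per μg g⁻¹
    b: float  # intercept, counts/cm²
    sigma_fit: float  # residual standard error, counts/cm²
    r2: float
    n: int
    level: float
    lod_conc: float  # μg g⁻¹
    loq_conc: float  # μg g⁻¹
    x_mean: float
    sxx: float
    cov_params: np.ndarray  # 2×2 covariance of (b, m)
    intercept_ci: tuple[float, float]
    origin_in_intercept_ci: bool
    weighted: bool = False
    x_values: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)

    @property
    def t_crit(self) -> float:
        return float(sps.t.ppf(0.5 + self.level / 2.0, self.n - 2))

    def predict_response(self, x):
        return self.m * np.asarray(x, dtype=float) + self.b


def points_from_frame(df: pd.DataFrame) -> list[CalibrationPoint]:
    """Build calibration points from a table with columns
    sample_id, concentration_ug_g, svalue_counts_cm2 and optional group."""
    pts = []
    for _, row in df.iterrows():
        pts.append(
            CalibrationPoint(
                sample_id=str(row["sample_id"]),
                concentration=float(row["concentration_ug_g"]),
                svalue=float(row["svalue_counts_cm2"]),
                group=str(row["group"]) if "group" in df.columns else None,
            )
        )
    return pts


def fit_calibration(
    points: Sequence[CalibrationPoint],
    level: float = 0.70,
    weighted: bool = False,
) -> CalibrationModel:
    """OLS fit of svalue against concentration with a free intercept.

    The intercept is estimated, not forced through the origin; the model
    records whether zero lies inside the intercept's confidence interval at
    ``level``, which is the origin-consistency check one expects of a sound
    signal-extraction chain.  ``weighted=True`` uses 1/x weights (points at
    x = 0 get the smallest positive design weight).
    """
    if len(points) < 3:
        raise ValueError("need at least 3 calibration points")
    x = np.array([p.concentration for p in points], dtype=float)
    y = np.array([p.svalue for p in points], dtype=float)
    return fit_calibration_xy(x, y, level=level, weighted=weighted)


def fit_calibration_xy(
    x: np.ndarray,
    y: np.ndarray,
    level: float = 0.70,
    weighted: bool = False,
) -> CalibrationModel:
    """Array-based variant of :func:`fit_calibration` (same model)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 calibration points")
    if np.unique(x).size < 2:
        raise ValueError("degenerate design: all concentrations equal")
    X = sm.add_constant(x)
    if weighted:
        pos = x[x > 0]
        w = 1.0 / np.where(x > 0, x, pos.min() if pos.size else 1.0)
        res = sm.WLS(y, X, weights=w).fit()
    else:
        res = sm.OLS(y, X).fit()
    n = x.size
    b, m = float(res.params[0]), float(res.params[1])
    sigma_fit = float(np.sqrt(res.ssr / (n - 2)))
    r2 = float(res.rsquared)
    ci = res.conf_int(alpha=1.0 - level)
    intercept_ci = (float(ci[0][0]), float(ci[0][1]))
    if m > 0 and sigma_fit >= 0:
        lod_conc = 3.3 * sigma_fit / m
        loq_conc = 10.0 * sigma_fit / m
    else:
        lod_conc = loq_conc = float("nan")
    return CalibrationModel(
        m=m,
        b=b,
        sigma_fit=sigma_fit,
        r2=r2,
        n=n,
        level=level,
        lod_conc=lod_conc,
        loq_conc=loq_conc,
        x_mean=float(x.mean()),
        sxx=float(((x - x.mean()) ** 2).sum()),
        cov_params=np.asarray(res.cov_params()),
        intercept_ci=intercept_ci,
        origin_in_intercept_ci=bool(intercept_ci[0] <= 0.0 <= intercept_ci[1]),
        weighted=weighted,
        x_values=x,
    )


def method_lod_loq(model: CalibrationModel) -> tuple[float, float]:
    """Concentration-domain detection limits: (3.3·σ_fit/m, 10·σ_fit/m)."""
    if model.m <= 0:
        raise ValueError("non-positive slope")
    return 3.3 * model.sigma_fit / model.m, 10.0 * model.sigma_fit / model.m


def confidence_band(model: CalibrationModel, x) -> tuple[np.ndarray, np.ndarray]:
    """Mean-response confidence band at the model's level.

    Half-width at x is t·σ_fit·√(1/n + (x − x̄)²/S_xx) — the standard
    hat-value form, symmetric around the fitted line.
    """
    if model.n <= 2:
        raise ValueError("need n > 2 for a confidence band")
    x = np.asarray(x, dtype=float)
    fit = model.predict_response(x)
    half = model.t_crit * model.sigma_fit * np.sqrt(
        1.0 / model.n + (x - model.x_mean) ** 2 / model.sxx
    )
    return fit - half, fit + half


def sigma_cc(model: CalibrationModel, points: Sequence[CalibrationPoint]) -> float:
    """Relative confidence-band half-width at the median design concentration,
    in percent (the σ_CC component of the uncertainty budget)."""
    x_med = float(np.median([p.concentration for p in points]))
    pred = model.predict_response(x_med)
    if pred <= 0:
        raise ValueError("predicted response at the median concentration is not positive")
    lower, upper = confidence_band(model, x_med)
    half = float(upper - lower) / 2.0
    return half / float(pred) * 100.0


@dataclass
class ConcentrationPrediction:
    concentration: float  # μg g⁻¹, clipped at 0
    sd: float  # first-order propagated SD, μg g⁻¹
    flags: tuple[str, ...]


def predict_concentration(model: CalibrationModel, svalue: float) -> ConcentrationPrediction:
    """Invert the calibration line: x̂ = (svalue − b)/m.

    The uncertainty is first-order propagation of the (b, m) covariance
    through the inverse; predictions below the method LoQ or LoD are flagged
    rather than suppressed, and a negative inverse is reported as 0.
    """
    if model.m <= 0:
        raise ValueError("non-positive slope")
    xhat = (svalue - model.b) / model.m
    cov = model.cov_params
    var = (cov[0, 0] + xhat**2 * cov[1, 1] + 2 * xhat * cov[0, 1]) / model.m**2
    sd = float(np.sqrt(max(var, 0.0)))
    flags: list[str] = []
    if xhat < 0:
        flags.append("negative estimate clipped to 0")
        xhat = 0.0
    if np.isfinite(model.lod_conc) and xhat < model.lod_conc:
        flags.append("not detected (below method LoD)")
    elif np.isfinite(model.loq_conc) and xhat < model.loq_conc:
        flags.append("below method LoQ")
    return ConcentrationPrediction(concentration=float(xhat), sd=sd, flags=tuple(flags))
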