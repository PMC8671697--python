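"""Weibull survival curves, per-cycle transition probabilities, and curve fitting.

The engine models time-to-event with the two-parameter Weibull survival
function

    S(t) = exp(-lambda * t**gamma)

where ``lambda`` (scale, month^-gamma) sets the overall event rate and
``gamma`` (shape, dimensionless) the hazard trend: gamma > 1 means a hazard
that rises with time, as is typical for progression and death in advanced
carcinoma cohorts. The per-cycle transition probability between consecutive
monthly cycles follows as

    P(t) = 1 - S(t)/S(t-1) = 1 - exp(lambda*(t-1)**gamma - lambda*t**gamma)

Parameters are either supplied directly (the base-case route) or estimated
from digitized Kaplan-Meier point series with :func:`fit_weibull`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "WeibullParams",
    "SurvivalCurveData",
    "FitDegenerateError",
    "InsufficientDataError",
    "survival_at",
    "cycle_transition_prob",
    "weibull_median",
    "fit_weibull",
    "read_curve_csv",
    "write_curve_csv",
]


class FitDegenerateError(ValueError):
    """All usable points sit at survival 0 or 1; the fit is unidentified."""


class InsufficientDataError(ValueError):
    """Fewer usable points than the fit requires."""


@dataclass(frozen=True)
class WeibullParams:
    """Scale/shape pair for one survival endpoint of one arm.

    ``se_*`` and ``ci_*`` carry the estimation uncertainty when the pair
    came from a fit; they default to zero/degenerate for fixed inputs.
    """

    scale: float
    shape: float
    se_scale: float = 0.0
    se_shape: float = 0.0
    ci_scale: tuple[float, float] | None = None
    ci_shape: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not (self.scale > 0 and self.shape > 0):
            raise ValueError(
                f"Weibull scale and shape must be positive, got "
                f"scale={self.scale}, shape={self.shape}"
            )
        if self.se_scale < 0 or self.se_shape < 0:
            raise ValueError("standard errors must be non-negative")
        for ci, est, name in (
            (self.ci_scale, self.scale, "scale"),
            (self.ci_shape, self.shape, "shape"),
        ):
            if ci is not None and not (ci[0] <= est <= ci[1]):
                raise ValueError(
                    f"{name} CI {ci} does not bracket the point estimate {est}"
                )

    @property
    def median(self) -> float:
        """Time (months) at which S(t) = 0.5."""
        return weibull_median(self)


@dataclass
class SurvivalCurveData:
    """Digitized (time, survival) point series read off a Kaplan-Meier figure."""

    points: list[tuple[float, float]]
    endpoint_label: str = "PFS"
    arm_label: str = ""

    def __post_init__(self) -> None:
        if self.endpoint_label not in ("PFS", "OS"):
            raise ValueError("endpoint_label must be 'PFS' or 'OS'")
        times = [t for t, _ in self.points]
        survs = [s for _, s in self.points]
        if any(t < 0 for t in times):
            raise ValueError("times must be non-negative")
        if any(not 0.0 <= s <= 1.0 for s in survs):
            raise ValueError("survival fractions must lie in [0, 1]")
        if any(t1 >= t2 for t1, t2 in zip(times, times[1:])):
            raise ValueError("times must be strictly increasing")
        if any(s1 < s2 - 1e-12 for s1, s2 in zip(survs, survs[1:])):
            raise ValueError("survival must be non-increasing")

    @property
    def times(self) -> np.ndarray:
        return np.array([t for t, _ in self.points], dtype=float)

    @property
    def survival(self) -> np.ndarray:
        return np.array([s for _, s in self.points], dtype=float)


def survival_at(t, params: WeibullParams):
    """Weibull survival probability S(t) = exp(-scale * t**shape).

    Accepts a scalar or array of times in months; S(0) = 1 exactly.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    out = np.exp(-params.scale * t**params.shape)
    return float(out) if out.ndim == 0 else out


def cycle_transition_prob(t, params: WeibullParams):
    """Probability of the event during cycle t given event-free at t-1.

    P(t) = 1 - exp(scale*(t-1)**shape - scale*t**shape) = 1 - S(t)/S(t-1),
    for integer cycle index t >= 1.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 1):
        raise ValueError("cycle index must be >= 1")
    out = 1.0 - np.exp(params.scale * (t - 1) ** params.shape - params.scale * t**params.shape)
    return float(out) if out.ndim == 0 else out


def weibull_median(params: WeibullParams) -> float:
    """Closed-form median survival time: (ln 2 / scale)**(1/shape)."""
    return (math.log(2.0) / params.scale) ** (1.0 / params.shape)


def _usable(curve: SurvivalCurveData) -> tuple[np.ndarray, np.ndarray]:
    """Points with t > 0 and survival strictly inside (0, 1)."""
    t, s = curve.times, curve.survival
    keep = (t > 0) & (s > 0.0) & (s < 1.0)
    return t[keep], s[keep]


def _linearized_fit(t: np.ndarray, s: np.ndarray) -> tuple[float, float]:
    """OLS on the complementary-log-log line log(-log S) = log scale + shape*log t.

    Exact for two points; used as the initializer for the direct fit.
    """
    y = np.log(-np.log(s))
    x = np.log(t)
    A = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(np.exp(coef[0])), float(coef[1])


def fit_weibull(curve: SurvivalCurveData, method: str = "direct") -> WeibullParams:
    """Estimate Weibull scale/shape from a digitized survival curve.

    method="direct" (default): nonlinear least squares on S(t) itself,
    initialized from the linearized fit; points at survival exactly 0 or 1
    are kept (they are informative for the direct loss) but t=0 is dropped.
    method="linearized": the complementary-log-log OLS line alone, which
    solves the two-point case exactly.

    Standard errors come from the fit covariance; 95% CIs are
    estimate +/- 1.96*SE on the working scale.
    """
    if method not in ("direct", "linearized"):
        raise ValueError(f"unknown fit method {method!r}")
    t_lin, s_lin = _usable(curve)
    if len(t_lin) == 0:
        raise FitDegenerateError(
            "no points with survival strictly between 0 and 1; Weibull fit is unidentified"
        )
    if len(t_lin) == 1:
        raise InsufficientDataError("need at least 2 usable points, got 1")

    lam0, gam0 = _linearized_fit(t_lin, s_lin)

    # two exact points: the linearized 2x2 system is square, solve it exactly
    if method == "linearized" or len(t_lin) == 2:
        return WeibullParams(
            scale=lam0,
            shape=gam0,
            ci_scale=(lam0, lam0),
            ci_shape=(gam0, gam0),
        )

    # direct loss keeps 0/1-survival points (excluding t=0)
    tt, ss = curve.times, curve.survival
    keep = tt > 0
    tt, ss = tt[keep], ss[keep]

    def model(t, log_lam, gam):
        return np.exp(-np.exp(log_lam) * t**gam)

    # optimize log(scale) to keep the parameter positive and well-scaled
    popt, pcov = optimize.curve_fit(
        model,
        tt,
        ss,
        p0=[np.log(lam0), gam0],
        maxfev=20000,
    )
    log_lam, gam = popt
    lam = float(np.exp(log_lam))
    se_log_lam, se_gam = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    se_lam = lam * float(se_log_lam)  # delta method back to the scale axis
    lo_lam = lam * math.exp(-1.96 * float(se_log_lam))
    hi_lam = lam * math.exp(1.96 * float(se_log_lam))
    return WeibullParams(
        scale=lam,
        shape=float(gam),
        se_scale=se_lam,
        se_shape=float(se_gam),
        ci_scale=(lo_lam, hi_lam),
        ci_shape=(float(gam - 1.96 * se_gam), float(gam + 1.96 * se_gam)),
    )


def read_curve_csv(path: str | Path, endpoint_label: str = "PFS", arm_label: str = "") -> SurvivalCurveData:
    """Read a digitized curve from 2-column CSV (time_months, survival), header required."""
    import pandas as pd

    df = pd.read_csv(path)
    expected = ["time_months", "survival"]
    if list(df.columns[:2]) != expected:
        raise ValueError(f"expected columns {expected}, got {list(df.columns)}")
    pts = list(zip(df["time_months"].astype(float), df["survival"].astype(float)))
    return SurvivalCurveData(points=pts, endpoint_label=endpoint_label, arm_label=arm_label)


def write_curve_csv(curve: SurvivalCurveData, path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(curve.points, columns=["time_months", "survival"]).to_csv(path, index=False)
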