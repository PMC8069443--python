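"""Wood's incomplete-gamma lactation curve.

The model describes daily yield as ``y(t) = a * t**b * exp(-c * t)`` with
``t`` the days in milk (DIM).  ``a`` scales yield near the start of
lactation, ``b`` governs the rise to peak and ``c`` the exponential
decline after it; the peak sits at ``t = b / c``.  The 305-day cow
literature and the goat literature alike fit this curve to test-day
records and integrate it to obtain lactation totals; here the horizon is
a 210-day goat lactation.

All daily yields are in g/day; totals are returned in kg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, optimize, special

__all__ = [
    "WoodParameters",
    "WoodFit",
    "CurveFeatures",
    "wood_predict",
    "log_linear_init",
    "fit_wood",
    "curve_features",
    "total_yield_wood",
    "total_yield_daily_sum",
    "InsufficientDataError",
    "DegenerateDataError",
]


class InsufficientDataError(ValueError):
    """Fewer usable points than the three free parameters require."""


class DegenerateDataError(ValueError):
    """Input data carry no usable signal (e.g. all-zero yields)."""


@dataclass(frozen=True)
class WoodParameters:
    """Parameter triple (a, b, c) of the Wood curve.

    a : scale of early yield, same units as the fitted series (g/day)
    b : unitless rate of increase to the peak
    c : per-day rate of decline after the peak
    """

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if not (self.a > 0):
            raise ValueError(f"Wood parameter a must be positive, got {self.a}")

    def to_dict(self) -> dict:
        return {"a": self.a, "b": self.b, "c": self.c}


@dataclass
class WoodFit:
    """Result of a nonlinear least-squares fit of the Wood curve."""

    params: WoodParameters
    r2: float
    n_points: int
    residuals: np.ndarray = field(repr=False)
    trait: str = "milk"
    converged: bool = True
    message: str = ""

    def __post_init__(self) -> None:
        if len(self.residuals) != self.n_points:
            raise ValueError("residuals length must equal n_points")
        if self.r2 > 1 + 1e-12:
            raise ValueError(f"r2 cannot exceed 1, got {self.r2}")


@dataclass(frozen=True)
class CurveFeatures:
    """Derived curve summaries: peak day, peak daily yield, persistency.

    Persistency is Wood's classical index ``c**-(b + 1)``; larger values
    mean a flatter post-peak decline.
    """

    peak_time: float
    peak_yield: float
    persistency: float


def wood_predict(params: WoodParameters, t):
    """Daily yield ``a * t**b * exp(-c*t)`` at DIM ``t`` (scalar or array).

    ``t`` must be strictly positive: at ``t = 0`` the power ``t**b`` is
    undefined for negative ``b``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("days in milk must be strictly positive")
    out = params.a * t**params.b * np.exp(-params.c * t)
    return float(out) if out.ndim == 0 else out


def _clean_points(t, y):
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("t and y must be 1-d arrays of equal length")
    if np.any(t <= 0):
        raise ValueError("days in milk must be strictly positive")
    return t, y


def log_linear_init(t, y) -> WoodParameters:
    """Closed-form initialization by log-linearization.

    OLS on ``ln y = ln a + b ln t - c t``; exact on noiseless Wood data,
    so it is both the optimizer's starting point and a fitting mode of
    its own.  Points with ``y <= 0`` cannot enter the log and are
    dropped; at least three must remain.
    """
    t, y = _clean_points(t, y)
    keep = y > 0
    t, y = t[keep], y[keep]
    if t.size < 3 or np.unique(t).size < 3:
        raise InsufficientDataError(
            f"need >= 3 positive-yield points at distinct DIM, have {t.size}"
        )
    X = np.column_stack([np.ones_like(t), np.log(t), t])
    beta, *_ = np.linalg.lstsq(X, np.log(y), rcond=None)
    return WoodParameters(a=float(np.exp(beta[0])), b=float(beta[1]), c=float(-beta[2]))


def _residuals(p, t, y):
    return y - p[0] * t ** p[1] * np.exp(-p[2] * t)


def _jacobian(p, t, y):
    f = t ** p[1] * np.exp(-p[2] * t)
    return np.column_stack([-f, -p[0] * f * np.log(t), p[0] * f * t])


def fit_wood(
    t,
    y,
    trait: str = "milk",
    *,
    log_linear_only: bool = False,
    xtol: float = 1e-10,
    max_nfev: int = 500,
) -> WoodFit:
    """Fit the Wood curve to test-day points by nonlinear least squares.

    Minimizes the raw-scale sum of squares with Levenberg–Marquardt,
    started from :func:`log_linear_init`.  ``r2`` is the raw-scale
    ``1 - SSE/SST`` over exactly the points fitted, so fits on reduced
    recording schedules have their own SST.  ``log_linear_only=True``
    skips the nonlinear refinement and scores the initialization.

    Non-convergence is not raised: the fit is returned flagged
    (``converged=False``) carrying the best parameters found.
    """
    t, y = _clean_points(t, y)
    if t.size < 3 or np.unique(t).size < 3:
        raise InsufficientDataError(
            f"need >= 3 points at distinct DIM, have {t.size}"
        )
    if np.all(y == 0):
        raise DegenerateDataError("all yields are zero")

    p0 = log_linear_init(t, y)
    x0 = np.array([p0.a, p0.b, p0.c])
    if log_linear_only:
        params, converged, message = p0, True, "log-linear OLS"
    else:
        res = optimize.least_squares(
            _residuals,
            x0,
            jac=_jacobian,
            method="lm",
            args=(t, y),
            xtol=xtol,
            ftol=xtol,
            gtol=xtol,
            max_nfev=max_nfev,
        )
        if res.success and res.x[0] > 0:
            params = WoodParameters(*[float(v) for v in res.x])
            converged, message = True, res.message
        else:
            # flagged fit: fall back to the initialization values
            params, converged, message = p0, False, res.message

    resid = _residuals(np.array([params.a, params.b, params.c]), t, y)
    sse = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if sst == 0 and sse == 0 else 1.0 - sse / sst if sst > 0 else -math.inf
    return WoodFit(
        params=params,
        r2=min(r2, 1.0),
        n_points=int(t.size),
        residuals=resid,
        trait=trait,
        converged=converged,
        message=str(message),
    )


def curve_features(params: WoodParameters) -> CurveFeatures:
    """Peak day b/c, peak daily yield, and persistency c^-(b+1).

    A curve with ``b <= 0`` or ``c <= 0`` has no interior maximum on
    (0, inf); peak_time is reported as 0 and peak_yield as the ``t -> 0+``
    limit behaviour evaluated at the first day (t=1).
    """
    if params.b > 0 and params.c > 0:
        peak_t = params.b / params.c
        peak_y = wood_predict(params, peak_t)
    else:
        peak_t = 0.0
        peak_y = wood_predict(params, 1.0)
    pers = params.c ** -(params.b + 1) if params.c > 0 else math.inf
    return CurveFeatures(peak_time=float(peak_t), peak_yield=float(peak_y), persistency=float(pers))


def total_yield_wood(params: WoodParameters, t_start: float, t_end: float) -> float:
    """Total yield (kg) over [t_start, t_end] by exact integration.

    For ``c > 0`` the integral of ``a t^b e^{-ct}`` is evaluated in
    closed form through the lower incomplete gamma function:
    ``(a / c**(b+1)) * (gamma_low(b+1, c*t_end) - gamma_low(b+1, c*t_start))``.
    For ``c <= 0`` (a fit that never turned downward — possible on noisy
    reduced schedules) the finite interval is integrated numerically.
    """
    if not (0 <= t_start < t_end):
        raise ValueError("require 0 <= t_start < t_end")
    s = params.b + 1.0
    if s <= 0 and t_start == 0:
        raise ValueError("integral diverges at 0 for b <= -1")
    if params.c > 0 and s > 0:
        scale = params.a / params.c**s * special.gamma(s)
        grams = scale * (
            special.gammainc(s, params.c * t_end)
            - special.gammainc(s, params.c * t_start)
        )
    else:
        lo = t_start if t_start > 0 else 1e-12
        grams, _ = integrate.quad(
            lambda u: params.a * u**params.b * np.exp(-params.c * u),
            lo,
            t_end,
            limit=200,
        )
    return float(grams) / 1000.0


def total_yield_daily_sum(params: WoodParameters, horizon_days: int = 210) -> float:
    """Alternative total (kg): sum of predicted daily yields t = 1..horizon."""
    t = np.arange(1, horizon_days + 1, dtype=float)
    return float(np.sum(wood_predict(params, t))) / 1000.0
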