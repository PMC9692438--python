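"""One-step growth curve (OSGC) analysis via the 4-parameter logistic model.

A synchronized single round of phage infection produces a sigmoidal
log-titer time course.  On the log10 scale the model is

    log10 P(t) = p_inf + (p0 - p_inf) / (1 + (t/a)^b)

with p0 the baseline log-titer, p_inf the post-burst plateau, a the
inflection time (minutes) and b the Hill slope.  From the fitted curve
the classical growth parameters are read off as rise-fraction crossing
times: the eclipse period is the time at which the curve has completed
a small fraction f_lo of its total rise, the latent period the time at
fraction f_hi, the intracellular accumulation period their difference,
and the burst size the plateau-to-baseline titer ratio 10^(p_inf - p0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import DegenerateFitError, FitError, InputError
from .fitstats import LackOfFitResult, ReplicatedSeries, lack_of_fit_test

__all__ = [
    "GrowthCurve",
    "FourPLFit",
    "GrowthParameters",
    "four_pl",
    "fit_4pl",
    "extract_growth_parameters",
    "read_growth_csv",
]

DEFAULT_OSGC_TIMES_MIN = np.arange(0, 91, 5, dtype=float)  # 0, 5, ..., 90 min


@dataclass(frozen=True)
class GrowthCurve:
    """Replicated log10-titer observations over time (long form).

    ``times_min`` and ``log_titers`` are parallel arrays with one entry
    per observation; replicate observations repeat their time point.
    """

    times_min: np.ndarray
    log_titers: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_min, dtype=float)
        y = np.asarray(self.log_titers, dtype=float)
        if t.ndim != 1 or t.shape != y.shape:
            raise InputError("times and log titers must be parallel 1-D arrays")
        if np.any(t < 0):
            raise InputError("times must be non-negative")
        if not np.all(np.isfinite(y)):
            raise InputError("log titers must be finite")
        if np.unique(t).size < 5:
            raise InputError("need at least 5 distinct time points to fit 4 parameters")
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "log_titers", y)

    def as_series(self) -> ReplicatedSeries:
        return ReplicatedSeries(self.times_min, self.log_titers)


@dataclass(frozen=True)
class FourPLFit:
    """Fitted 4-PL parameters with residual diagnostics."""

    p0: float
    p_inf: float
    a: float
    b: float
    sse: float
    fitted: np.ndarray
    times_min: np.ndarray
    n_obs: int
    converged: bool
    cov: np.ndarray | None = None
    n_restarts_used: int = 0

    @property
    def params(self) -> np.ndarray:
        return np.array([self.p0, self.p_inf, self.a, self.b])

    def predict(self, t) -> np.ndarray:
        return four_pl(t, self.p0, self.p_inf, self.a, self.b)

    def standard_errors(self) -> np.ndarray | None:
        if self.cov is None:
            return None
        return np.sqrt(np.clip(np.diag(self.cov), 0, None))

    def lack_of_fit(self, curve: GrowthCurve, alpha: float = 0.05) -> LackOfFitResult:
        return lack_of_fit_test(curve.as_series(), lambda t: float(self.predict(t)), 4, alpha)


def four_pl(t, p0: float, p_inf: float, a: float, b: float):
    """Evaluate the 4-parameter logistic on the log10-titer scale.

    Equals ``p0`` at t=0 and tends to ``p_inf`` as t grows; the
    midpoint (p0+p_inf)/2 is reached at t = a.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise InputError("time must be non-negative")
    if a <= 0 or b <= 0:
        raise InputError("a and b must be positive")
    with np.errstate(divide="ignore"):
        ratio = np.where(t_arr > 0, (t_arr / a) ** b, 0.0)
    out = p_inf + (p0 - p_inf) / (1.0 + ratio)
    return out if out.shape else float(out)


def _pl4_residuals(theta, t, y):
    p0, p_inf, a, b = theta
    with np.errstate(divide="ignore"):
        ratio = np.where(t > 0, (t / a) ** b, 0.0)
    return p_inf + (p0 - p_inf) / (1.0 + ratio) - y


def fit_4pl(
    curve: GrowthCurve,
    init: tuple[float, float, float, float] | None = None,
    flat_epsilon: float = 1e-3,
    n_restarts: int = 3,
    seed: int = 0,
) -> FourPLFit:
    """Least-squares fit of the 4-PL model to a growth curve.

    Initial values default to the observed min/max log-titers for
    p0/p_inf, the midpoint-crossing time for a, and Hill slope 5; on a
    poor optimum the fit is restarted from jittered initial values.
    """
    t = curve.times_min
    y = curve.log_titers
    pts, means, _ = curve.as_series().group_means()
    if means.max() - means.min() < flat_epsilon:
        raise DegenerateFitError(
            "log-titer dynamic range below epsilon; 4-PL fit is degenerate"
        )

    if init is None:
        p0_0 = float(means.min())
        pinf_0 = float(means.max())
        mid = (p0_0 + pinf_0) / 2
        above = pts[means >= mid]
        a0 = float(above[0]) if above.size and above[0] > 0 else float(np.median(pts[pts > 0]))
        init = (p0_0, pinf_0, a0, 5.0)

    lo = [-np.inf, -np.inf, 1e-9, 1e-9]
    hi = [np.inf, np.inf, np.inf, np.inf]
    rng = np.random.default_rng(seed)

    def solve(theta0):
        theta0 = np.clip(theta0, lo, hi)
        return least_squares(
            _pl4_residuals, theta0, args=(t, y), bounds=(lo, hi),
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )

    best = solve(np.asarray(init, dtype=float))
    restarts = 0
    # restart from jittered inits if the optimizer stalled at a poor optimum
    while restarts < n_restarts and (not best.success or not np.isfinite(best.cost)):
        restarts += 1
        jitter = 1.0 + 0.2 * rng.standard_normal(4)
        best = solve(np.asarray(init, dtype=float) * jitter)
    if not best.success:
        raise FitError(f"4-PL fit did not converge: {best.message}")

    sse = float(2 * best.cost)
    fitted = _pl4_residuals(best.x, t, np.zeros_like(y))  # model values at t
    dof = max(t.size - 4, 1)
    jtj = best.jac.T @ best.jac
    try:
        cov = np.linalg.inv(jtj) * sse / dof
    except np.linalg.LinAlgError:
        cov = None
    return FourPLFit(
        p0=float(best.x[0]),
        p_inf=float(best.x[1]),
        a=float(best.x[2]),
        b=float(best.x[3]),
        sse=sse,
        fitted=fitted,
        times_min=t,
        n_obs=t.size,
        converged=True,
        cov=cov,
        n_restarts_used=restarts,
    )


@dataclass(frozen=True)
class GrowthParameters:
    """Classical OSGC growth parameters derived from a 4-PL fit."""

    eclipse_min: float
    latent_min: float
    accumulation_min: float
    burst_size: float
    rise_fractions: tuple[float, float] = (0.05, 0.95)
    # burst size is the plateau-to-baseline titer ratio; it assumes every
    # input phage infected a cell, which the low-MOI OSGC design approximates
    definition: str = field(default="burst_size = 10^(p_inf - p0)", repr=False)


def extract_growth_parameters(
    fit: FourPLFit, f_lo: float = 0.05, f_hi: float = 0.95
) -> GrowthParameters:
    """Read eclipse/latent/accumulation periods and burst size off a fit.

    The time at which the fitted curve completes a fraction f of its
    rise from p0 to p_inf is t(f) = a * (f / (1-f))^(1/b); eclipse and
    latent periods are t(f_lo) and t(f_hi).
    """
    if not (0 < f_lo < f_hi < 1):
        raise InputError("need 0 < f_lo < f_hi < 1")
    if fit.p_inf <= fit.p0:
        raise FitError("plateau does not exceed baseline: no growth to parameterize")
    eclipse = fit.a * (f_lo / (1 - f_lo)) ** (1 / fit.b)
    latent = fit.a * (f_hi / (1 - f_hi)) ** (1 / fit.b)
    return GrowthParameters(
        eclipse_min=eclipse,
        latent_min=latent,
        accumulation_min=latent - eclipse,
        burst_size=10.0 ** (fit.p_inf - fit.p0),
        rise_fractions=(f_lo, f_hi),
    )


def read_growth_csv(path, log_transform: bool | None = None) -> GrowthCurve:
    """Read an OSGC table with columns time_min, rep, log10_pfu_per_ml.

    A ``pfu_per_ml`` column is accepted instead, in which case titers
    are log10-transformed (zero titers rejected).
    """
    df = pd.read_csv(path, comment="#")
    if "log10_pfu_per_ml" in df.columns:
        y = df["log10_pfu_per_ml"].to_numpy(dtype=float)
    elif "pfu_per_ml" in df.columns:
        raw = df["pfu_per_ml"].to_numpy(dtype=float)
        if np.any(raw <= 0):
            raise InputError("pfu_per_ml must be positive for log transform")
        y = np.log10(raw)
    else:
        raise InputError("need a log10_pfu_per_ml or pfu_per_ml column")
    if "time_min" not in df.columns:
        raise InputError("need a time_min column")
    return GrowthCurve(df["time_min"].to_numpy(dtype=float), y)
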