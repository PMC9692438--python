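"""Goodness-of-fit machinery shared by the nonlinear fitting modules.

Implements the replicated lack-of-fit F-test (pure-error vs lack-of-fit
decomposition of the residual sum of squares), the coefficient of
determination, and pointwise confidence bands for fitted curves.

The lack-of-fit test requires genuine replication: with n observations
at m distinct design points and a p-parameter model,

    SS_pe  = sum over points of sum over reps (y - group mean)^2,   df = n - m
    SS_lof = sum over points of n_reps * (group mean - fitted)^2,   df = m - p
    F      = (SS_lof / df_lof) / (SS_pe / df_pe)

and F is referred to the F(df_lof, df_pe) distribution; a small F (large
p-value) means the scatter of the group means about the fitted curve is
comparable to replicate noise, i.e. no evidence of lack of fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import FitError, InputError, NotApplicableError

__all__ = [
    "ReplicatedSeries",
    "LackOfFitResult",
    "lack_of_fit_test",
    "r_squared",
    "confidence_band",
]


@dataclass(frozen=True)
class ReplicatedSeries:
    """Long-form replicated observations: y_i observed at design point x_i."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise InputError("x and y must be 1-D arrays of equal length")
        if x.size == 0:
            raise InputError("empty series")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @property
    def design_points(self) -> np.ndarray:
        return np.unique(self.x)

    def group_means(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (distinct x, group mean of y, replicate count) sorted by x."""
        pts = self.design_points
        means = np.array([self.y[self.x == p].mean() for p in pts])
        counts = np.array([(self.x == p).sum() for p in pts])
        return pts, means, counts


@dataclass(frozen=True)
class LackOfFitResult:
    ss_lof: float
    ss_pe: float
    df_lof: int
    df_pe: int
    f_ratio: float
    f_critical: float
    p_value: float
    alpha: float
    degenerate: bool = False

    @property
    def no_lack_of_fit(self) -> bool:
        """True when the model is not rejected at level alpha."""
        if self.degenerate:
            return True
        return self.f_ratio < self.f_critical


def lack_of_fit_test(
    data: ReplicatedSeries,
    fitted,
    n_params: int,
    alpha: float = 0.05,
) -> LackOfFitResult:
    """Replicated lack-of-fit F-test of an already-fitted model.

    Parameters
    ----------
    data
        Replicated observations.
    fitted
        Model predictions, either one per distinct design point (in
        ascending x order) or one per observation (constant within a
        design point), or a callable evaluated at the design points.
    n_params
        Number of parameters the model was fitted with.
    alpha
        Significance level for the critical F value.
    """
    pts, means, counts = data.group_means()
    m = pts.size
    n = data.y.size
    if n <= m:
        raise NotApplicableError(
            "lack-of-fit test requires replication (more observations than design points)"
        )
    df_lof = m - n_params
    df_pe = n - m
    if df_lof < 1:
        raise NotApplicableError(
            f"model with {n_params} parameters is saturated for {m} design points"
        )

    if callable(fitted):
        fhat = np.asarray([float(fitted(p)) for p in pts])
    else:
        fitted = np.asarray(fitted, dtype=float)
        if fitted.shape == (m,):
            fhat = fitted
        elif fitted.shape == data.x.shape:
            fhat = np.array([fitted[data.x == p][0] for p in pts])
        else:
            raise InputError(
                "fitted must have one value per design point or per observation"
            )

    ss_pe = float(sum(((data.y[data.x == p] - mu) ** 2).sum() for p, mu in zip(pts, means)))
    ss_lof = float((counts * (means - fhat) ** 2).sum())

    f_critical = float(stats.f.ppf(1 - alpha, df_lof, df_pe))
    if ss_pe == 0.0:
        # replicates identical: pure error is zero and F is undefined
        degenerate = True
        f_ratio = np.nan if ss_lof == 0.0 else np.inf
        p_value = np.nan
    else:
        degenerate = False
        f_ratio = (ss_lof / df_lof) / (ss_pe / df_pe)
        p_value = float(stats.f.sf(f_ratio, df_lof, df_pe))
    return LackOfFitResult(
        ss_lof=ss_lof,
        ss_pe=ss_pe,
        df_lof=df_lof,
        df_pe=df_pe,
        f_ratio=float(f_ratio),
        f_critical=f_critical,
        p_value=p_value,
        alpha=alpha,
        degenerate=degenerate,
    )


def r_squared(observed, fitted) -> float:
    """Coefficient of determination, 1 - SSE / SStot about the observed mean."""
    obs = np.asarray(observed, dtype=float)
    fit = np.asarray(fitted, dtype=float)
    if obs.shape != fit.shape or obs.size < 2:
        raise InputError("need >= 2 paired observations")
    sstot = float(((obs - obs.mean()) ** 2).sum())
    if sstot == 0:
        raise InputError("observations have zero variance; r^2 undefined")
    sse = float(((obs - fit) ** 2).sum())
    return 1.0 - sse / sstot


def _numerical_jacobian(predict, params, x, rel_step=1e-6):
    params = np.asarray(params, dtype=float)
    base = np.asarray(predict(x, params), dtype=float)
    jac = np.empty((base.size, params.size))
    for j in range(params.size):
        h = rel_step * max(abs(params[j]), 1.0)
        up = params.copy()
        up[j] += h
        jac[:, j] = (np.asarray(predict(x, up)) - base) / h
    return base, jac


def confidence_band(
    predict,
    params,
    cov,
    x,
    level: float = 0.95,
    df: int | None = None,
    refit=None,
    data: tuple[np.ndarray, np.ndarray] | None = None,
    n_boot: int = 199,
    seed: int = 0,
    method: str = "delta",
) -> dict:
    """Pointwise confidence band for a fitted curve at abscissae ``x``.

    The default delta-method band propagates the parameter covariance
    through the numerically differentiated prediction function.  When
    the covariance is singular or non-finite and a ``refit`` callable
    plus the original ``data`` are supplied, a seeded percentile
    bootstrap (residual resampling) is used instead, with a warning.

    Returns a dict with keys x, fit, lower, upper, method, level.
    """
    if not 0 <= level < 1:
        raise InputError("confidence level must be in [0, 1)")
    x = np.atleast_1d(np.asarray(x, dtype=float))
    params = np.asarray(params, dtype=float)

    cov_ok = cov is not None and np.all(np.isfinite(cov))
    if method == "delta" and not cov_ok:
        if refit is not None and data is not None:
            warnings.warn(
                "parameter covariance unusable; falling back to bootstrap band",
                stacklevel=2,
            )
            method = "bootstrap"
        else:
            raise FitError("singular parameter covariance and no bootstrap fallback")

    if method == "delta":
        fit, jac = _numerical_jacobian(predict, params, x)
        var = np.einsum("ij,jk,ik->i", jac, np.asarray(cov, dtype=float), jac)
        var = np.clip(var, 0.0, None)
        if level == 0:
            q = 0.0
        elif df is not None:
            q = float(stats.t.ppf(0.5 + level / 2, df))
        else:
            q = float(stats.norm.ppf(0.5 + level / 2))
        half = q * np.sqrt(var)
        lower, upper = fit - half, fit + half
    elif method == "bootstrap":
        if refit is None or data is None:
            raise InputError("bootstrap band needs refit callable and data")
        xd, yd = data
        xd = np.asarray(xd, dtype=float)
        yd = np.asarray(yd, dtype=float)
        fit = np.asarray(predict(x, params), dtype=float)
        resid = yd - np.asarray(predict(xd, params), dtype=float)
        rng = np.random.default_rng(seed)
        curves = np.empty((n_boot, x.size))
        for b in range(n_boot):
            yb = np.asarray(predict(xd, params)) + rng.choice(resid, size=resid.size)
            pb = refit(xd, yb)
            curves[b] = np.asarray(predict(x, np.asarray(pb, dtype=float)))
        lo_q = (1 - level) / 2 * 100
        lower = np.percentile(curves, lo_q, axis=0)
        upper = np.percentile(curves, 100 - lo_q, axis=0)
    else:
        raise InputError(f"unknown confidence band method {method!r}")

    return {
        "x": x,
        "fit": np.asarray(predict(x, params), dtype=float),
        "lower": lower,
        "upper": upper,
        "method": method,
        "level": level,
    }
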