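"""Reversible phage-bacteria adsorption kinetics.

Free phage P and susceptible host cells (at fixed density X0) form a
reversible complex with mass-action attachment rate delta and
first-order release rate phi:

    P + X  --delta*X0-->  complex,      complex  --phi-->  P + X

With X0 constant, the fraction of phage still free at time t has the
closed form

    P(t)/P(0) = (phi + delta*X0 * exp(-(delta*X0 + phi) * t)) / (delta*X0 + phi)

which starts at 1, decays exponentially with rate delta*X0 + phi, and
levels off at the equilibrium free fraction phi / (delta*X0 + phi).

Units: delta is mL * CFU^-1 * min^-1 (so delta*X0 is min^-1) and phi is
min^-1; times are minutes.  Reported rate magnitudes from the
literature frequently carry ambiguous unit strings; an hour-based
interpretation simply rescales both rates by 60 and is left to the
caller (see ``docs/methods.md``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import FitError, InputError
from .fitstats import LackOfFitResult, ReplicatedSeries, lack_of_fit_test, r_squared

__all__ = [
    "AdsorptionCurve",
    "AdsorptionFit",
    "adsorption_model",
    "fit_adsorption",
    "adsorbed_percent",
    "read_adsorption_csv",
    "DEFAULT_ADSORPTION_TIMES_MIN",
]

# 5-min sampling to 30 min, then 10-min sampling to 150 min (19 points)
DEFAULT_ADSORPTION_TIMES_MIN = np.concatenate(
    [np.arange(0, 31, 5), np.arange(40, 151, 10)]
).astype(float)

FREE_FRACTION_CEILING = 1.2  # counting noise can push P_t/P_0 slightly above 1


@dataclass(frozen=True)
class AdsorptionCurve:
    """Replicated free-phage fractions P_t/P_0 over time, at fixed host density."""

    times_min: np.ndarray
    free_fraction: np.ndarray
    x0: float  # host density, CFU/mL

    def __post_init__(self) -> None:
        t = np.asarray(self.times_min, dtype=float)
        f = np.asarray(self.free_fraction, dtype=float)
        if t.ndim != 1 or t.shape != f.shape:
            raise InputError("times and fractions must be parallel 1-D arrays")
        if np.any(t < 0):
            raise InputError("times must be non-negative")
        if np.any(f < 0) or np.any(f > FREE_FRACTION_CEILING):
            raise InputError(
                f"free fractions must lie in [0, {FREE_FRACTION_CEILING}]"
            )
        if 0.0 not in t:
            raise InputError("time 0 must be present (normalization anchor)")
        if not self.x0 > 0:
            raise InputError("host density x0 must be positive")
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "free_fraction", f)

    def as_series(self) -> ReplicatedSeries:
        return ReplicatedSeries(self.times_min, self.free_fraction)


@dataclass(frozen=True)
class AdsorptionFit:
    """Fitted adsorption (delta) and desorption (phi) rates."""

    delta: float  # mL CFU^-1 min^-1
    phi: float  # min^-1
    x0: float
    r_squared: float
    sse: float
    residuals: np.ndarray
    converged: bool
    cov: np.ndarray | None = None
    no_adsorption: bool = False
    bounded_at_zero: bool = False

    @property
    def equilibrium_free_fraction(self) -> float:
        k = self.delta * self.x0 + self.phi
        return 1.0 if k == 0 else self.phi / k

    def predict(self, t):
        return adsorption_model(t, self.delta, self.phi, self.x0)

    def lack_of_fit(self, curve: AdsorptionCurve, alpha: float = 0.05) -> LackOfFitResult:
        return lack_of_fit_test(curve.as_series(), lambda t: float(self.predict(t)), 2, alpha)


def adsorption_model(t, delta: float, phi: float, x0: float):
    """Closed-form free-phage fraction under reversible adsorption.

    Returns (phi + delta*x0*exp(-(delta*x0+phi)*t)) / (delta*x0 + phi);
    identically 1 when both rates are zero.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise InputError("time must be non-negative")
    if delta < 0 or phi < 0:
        raise InputError("rates must be non-negative")
    k = delta * x0 + phi
    if k == 0:
        out = np.ones_like(t_arr)
    else:
        out = (phi + delta * x0 * np.exp(-k * t_arr)) / k
    return out if out.shape else float(out)


def _ads_residuals(theta, t, f, x0):
    delta, phi = theta
    k = delta * x0 + phi
    if k == 0:
        return 1.0 - f
    return (phi + delta * x0 * np.exp(-k * t)) / k - f


def fit_adsorption(
    curve: AdsorptionCurve,
    init: tuple[float, float] | None = None,
    n_restarts: int = 3,
    seed: int = 0,
) -> AdsorptionFit:
    """Bounded least-squares fit of (delta, phi) with x0 held fixed.

    Initial guesses derive from the observed half-decay time
    (delta0 = ln 2 / (x0 * t_half)) with phi0 = 0.1 * delta0 * x0;
    the optimizer restarts from jittered values if it stalls.
    """
    t = curve.times_min
    f = curve.free_fraction
    x0 = curve.x0
    pts, means, _ = curve.as_series().group_means()
    if np.unique(t).size < 4:
        raise InputError("need at least 4 distinct times to fit 2 rate parameters")

    if init is None:
        below = pts[means <= 0.5]
        t_half = float(below[0]) if below.size and below[0] > 0 else float(pts[-1]) / 2
        delta0 = np.log(2) / (x0 * max(t_half, 1e-9))
        init = (delta0, 0.1 * delta0 * x0)

    lo = [0.0, 0.0]
    hi = [np.inf, np.inf]
    rng = np.random.default_rng(seed)

    def solve(theta0):
        theta0 = np.clip(theta0, 1e-300, None)
        return least_squares(
            _ads_residuals, theta0, args=(t, f, x0), bounds=(lo, hi),
            xtol=1e-12, ftol=1e-12, gtol=1e-14, max_nfev=5000,
            x_scale=np.maximum(theta0, 1e-12),
        )

    best = solve(np.asarray(init, dtype=float))
    restarts = 0
    while restarts < n_restarts and not best.success:
        restarts += 1
        jitter = np.exp(0.3 * rng.standard_normal(2))
        best = solve(np.asarray(init, dtype=float) * jitter)
    if not best.success:
        raise FitError(f"adsorption fit did not converge: {best.message}")

    delta, phi = (float(v) for v in best.x)
    resid = _ads_residuals(best.x, t, f, x0)
    sse = float((resid**2).sum())
    try:
        r2 = r_squared(f, f + resid)
    except InputError:
        r2 = np.nan
    dof = max(t.size - 2, 1)
    jtj = best.jac.T @ best.jac
    try:
        cov = np.linalg.inv(jtj) * sse / dof
    except np.linalg.LinAlgError:
        cov = None
    k = delta * x0 + phi
    eq_free = 1.0 if k == 0 else phi / k
    no_adsorption = delta * x0 * float(t.max()) < 1e-6 or eq_free > 0.99
    return AdsorptionFit(
        delta=delta,
        phi=phi,
        x0=x0,
        r_squared=float(r2),
        sse=sse,
        residuals=resid,
        converged=True,
        cov=cov,
        no_adsorption=no_adsorption,
        bounded_at_zero=bool(delta == 0.0 or phi == 0.0),
    )


def adsorbed_percent(free_fraction) -> np.ndarray | float:
    """Percentage of phage adsorbed, 100 * (1 - free fraction)."""
    f = np.asarray(free_fraction, dtype=float)
    out = 100.0 * (1.0 - f)
    return out if out.shape else float(out)


def read_adsorption_csv(path, x0: float) -> AdsorptionCurve:
    """Read an adsorption table with columns time_min, rep, free_fraction.

    A ``pfu_per_ml`` column is accepted instead; each replicate series
    is then normalized by its own t=0 titer.
    """
    df = pd.read_csv(path, comment="#")
    if "time_min" not in df.columns:
        raise InputError("need a time_min column")
    if "free_fraction" in df.columns:
        frac = df["free_fraction"].to_numpy(dtype=float)
    elif "pfu_per_ml" in df.columns:
        if "rep" not in df.columns:
            raise InputError("pfu_per_ml input needs a rep column for normalization")
        frac = np.empty(len(df), dtype=float)
        for rep, grp in df.groupby("rep"):
            base_rows = grp[grp["time_min"] == 0]
            if base_rows.empty or base_rows["pfu_per_ml"].iloc[0] <= 0:
                raise InputError(f"replicate {rep!r} lacks a positive t=0 titer")
            base = float(base_rows["pfu_per_ml"].iloc[0])
            frac[grp.index] = grp["pfu_per_ml"].to_numpy(dtype=float) / base
    else:
        raise InputError("need a free_fraction or pfu_per_ml column")
    return AdsorptionCurve(df["time_min"].to_numpy(dtype=float), frac, x0=x0)
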