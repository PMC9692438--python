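"""UV extinction-coefficient calibration and cold-storage decay fitting.

Whole phage particles absorb in the UV (protein chromophores peak near
255-280 nm) but also scatter light; absorbance at 320 nm, where the
chromophores are essentially transparent, estimates the scattering
contribution and is subtracted from the 255 nm reading.  The corrected
absorbance of a dilution series is fitted to Beer-Lambert,
A = epsilon * c * l, giving a particle-count extinction coefficient
epsilon in (PFU/mL)^-1 cm^-1 that converts absorbance to titer.

Shelf stability of a phage formulation is summarized by fitting the
normalized lytic area A(t)/A(0) over storage time to a one-parameter
exponential decay exp(-t/tau); the decay rate is lambda = 1/tau and the
mean lifetime equals tau, so the reported pair is self-consistent by
construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import FitError, InputError
from .fitstats import r_squared

__all__ = [
    "DilutionSeries",
    "ExtinctionFit",
    "StorageSeries",
    "DecayFit",
    "corrected_absorbance",
    "fit_extinction",
    "titer_from_absorbance",
    "fit_storage_decay",
    "read_dilution_csv",
    "read_storage_csv",
]


def corrected_absorbance(a255, a320):
    """Scattering-corrected absorbance, a255 - a320.

    Negative results (a320 exceeding a255) are physically suspect and
    trigger a warning but are returned unchanged.
    """
    a255 = np.asarray(a255, dtype=float)
    a320 = np.asarray(a320, dtype=float)
    if np.any(a255 < 0) or np.any(a320 < 0):
        raise InputError("absorbances must be non-negative")
    out = a255 - a320
    if np.any(out < 0):
        warnings.warn(
            "corrected absorbance negative (A320 > A255); check for contamination",
            stacklevel=2,
        )
    return out if out.shape else float(out)


@dataclass(frozen=True)
class DilutionSeries:
    """Known-titer dilution series with raw 255/320 nm absorbances."""

    concentrations: np.ndarray  # PFU/mL
    a255: np.ndarray
    a320: np.ndarray
    path_length_cm: float = 1.0

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        a255 = np.asarray(self.a255, dtype=float)
        a320 = np.asarray(self.a320, dtype=float)
        if not (c.shape == a255.shape == a320.shape) or c.ndim != 1:
            raise InputError("concentrations and absorbances must be parallel 1-D arrays")
        if c.size < 3:
            raise InputError("need at least 3 dilution points")
        if np.any(c < 0):
            raise InputError("concentrations must be non-negative")
        if not self.path_length_cm > 0:
            raise InputError("path length must be positive")
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "a255", a255)
        object.__setattr__(self, "a320", a320)

    @property
    def corrected(self) -> np.ndarray:
        return corrected_absorbance(self.a255, self.a320)


@dataclass(frozen=True)
class ExtinctionFit:
    epsilon: float  # (PFU/mL)^-1 cm^-1
    intercept: float
    r_squared: float
    through_origin: bool
    path_length_cm: float = 1.0


def fit_extinction(series: DilutionSeries, through_origin: bool = True) -> ExtinctionFit:
    """Least-squares Beer-Lambert slope of corrected absorbance vs c*l.

    Through-origin by default (Beer-Lambert has no intercept); a free
    intercept is available for diagnosing baseline offsets.
    """
    x = series.concentrations * series.path_length_cm
    y = series.corrected
    if np.ptp(x) == 0:
        raise InputError("zero spread in concentrations; cannot calibrate")
    if through_origin:
        slope = float(np.dot(x, y) / np.dot(x, x))
        intercept = 0.0
    else:
        design = np.column_stack([x, np.ones_like(x)])
        (slope, intercept), *_ = np.linalg.lstsq(design, y, rcond=None)
        slope, intercept = float(slope), float(intercept)
    fitted = slope * x + intercept
    if slope <= 0:
        raise FitError("non-positive extinction coefficient; calibration invalid")
    try:
        r2 = r_squared(y, fitted)
    except InputError:
        r2 = np.nan
    return ExtinctionFit(
        epsilon=slope,
        intercept=intercept,
        r_squared=float(r2),
        through_origin=through_origin,
        path_length_cm=series.path_length_cm,
    )


def titer_from_absorbance(a_corr: float, fit: ExtinctionFit) -> float:
    """Invert the Beer-Lambert calibration: c = (A - intercept) / (epsilon * l)."""
    if fit.epsilon <= 0:
        raise InputError("extinction coefficient must be positive")
    return (a_corr - fit.intercept) / (fit.epsilon * fit.path_length_cm)


@dataclass(frozen=True)
class StorageSeries:
    """Normalized lytic-area ratios A(t)/A(0) over storage days."""

    days: np.ndarray
    ratios: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.days, dtype=float)
        r = np.asarray(self.ratios, dtype=float)
        if d.shape != r.shape or d.ndim != 1:
            raise InputError("days and ratios must be parallel 1-D arrays")
        if d.size < 3:
            raise InputError("need at least 3 storage points")
        if d[0] != 0:
            raise InputError("first storage point must be day 0")
        object.__setattr__(self, "days", d)
        object.__setattr__(self, "ratios", r)


@dataclass(frozen=True)
class DecayFit:
    """Exponential storage-decay fit, ratio(t) = exp(-t/tau)."""

    tau_days: float
    sse: float
    n_used: int
    no_decay: bool = False

    @property
    def lambda_per_day(self) -> float:
        return 0.0 if np.isinf(self.tau_days) else 1.0 / self.tau_days

    @property
    def mean_lifetime_days(self) -> float:
        return self.tau_days

    def predict(self, days):
        days = np.asarray(days, dtype=float)
        out = np.exp(-days / self.tau_days)
        return out if out.shape else float(out)


def fit_storage_decay(series: StorageSeries, nonlinear_refit: bool = False) -> DecayFit:
    """Fit exp(-t/tau) to normalized lytic areas.

    Default is a through-origin linear regression of ln ratio on time
    (exact for the one-parameter model; no iteration).  Non-positive
    ratios carry no log information and are excluded with a warning.
    An optional nonlinear refit minimizes squared error on the ratio
    scale instead, seeded from the linear estimate.
    """
    t = series.days
    r = series.ratios
    keep = r > 0
    if not np.all(keep):
        warnings.warn("non-positive area ratios excluded from decay fit", stacklevel=2)
    t_use, r_use = t[keep], r[keep]
    if t_use.size < 3:
        raise InputError("fewer than 3 usable (positive-ratio) points")
    log_r = np.log(r_use)
    denom = float(np.dot(t_use, t_use))
    if denom == 0:
        raise InputError("all usable points at day 0; no decay information")
    slope = float(np.dot(t_use, log_r) / denom)  # ln ratio = slope * t
    if slope >= 0:
        # flat or rising: no measurable decay
        sse = float(((r_use - 1.0) ** 2).sum())
        return DecayFit(tau_days=np.inf, sse=sse, n_used=int(t_use.size), no_decay=True)
    tau = -1.0 / slope
    if nonlinear_refit:
        popt, _ = curve_fit(lambda tt, tau_: np.exp(-tt / tau_), t_use, r_use, p0=[tau])
        tau = float(popt[0])
    sse = float(((r_use - np.exp(-t_use / tau)) ** 2).sum())
    return DecayFit(tau_days=float(tau), sse=sse, n_used=int(t_use.size))


def read_dilution_csv(path, path_length_cm: float = 1.0) -> DilutionSeries:
    """Read a dilution series with columns concentration_pfu_ml, a255, a320."""
    df = pd.read_csv(path, comment="#")
    required = {"concentration_pfu_ml", "a255", "a320"}
    if required - set(df.columns):
        raise InputError("dilution table needs concentration_pfu_ml, a255, a320 columns")
    return DilutionSeries(
        concentrations=df["concentration_pfu_ml"].to_numpy(dtype=float),
        a255=df["a255"].to_numpy(dtype=float),
        a320=df["a320"].to_numpy(dtype=float),
        path_length_cm=path_length_cm,
    )


def read_storage_csv(path) -> StorageSeries:
    """Read a storage series with columns day, normalized_area."""
    df = pd.read_csv(path, comment="#")
    if {"day", "normalized_area"} - set(df.columns):
        raise InputError("storage table needs day and normalized_area columns")
    df = df.sort_values("day")
    return StorageSeries(
        days=df["day"].to_numpy(dtype=float),
        ratios=df["normalized_area"].to_numpy(dtype=float),
    )
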