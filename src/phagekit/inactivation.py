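"""Killing-curve analytics: log reductions, phage amplification, regrowth.

A killing-curve experiment tracks four series on a shared time grid
(hours): the untreated bacterial control BC (CFU/mL), the treated
bacteria BP-B (CFU/mL), the cell-free phage control PC (PFU/mL) and the
phage co-incubated with bacteria BP-P (PFU/mL).  The per-time log10
reduction log10(BC) - log10(BP-B) quantifies the killing effect;
regrowth (rebound of the treated series, typically from phage-resistant
mutants) is declared by a threshold-and-persistence rule on the rise of
the treated series above its running minimum, or — when replicate
observations are available — by per-time Welch comparisons against the
running-minimum time point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, NotApplicableError

__all__ = [
    "KillingCurveSet",
    "ReductionProfile",
    "RegrowthResult",
    "log_reduction",
    "phage_amplification",
    "detect_regrowth",
    "detect_regrowth_replicates",
    "read_killcurve_csv",
]


@dataclass(frozen=True)
class KillingCurveSet:
    """Paired control/treatment series on one time grid (mean series).

    Optional ``replicates`` maps a series name ('bc', 'bp_b', 'pc',
    'bp_p') to an (n_times, n_reps) array of raw replicate values.
    """

    times_h: np.ndarray
    bc: np.ndarray  # bacterial control, CFU/mL
    bp_b: np.ndarray  # treated bacteria, CFU/mL
    pc: np.ndarray  # phage control, PFU/mL
    bp_p: np.ndarray  # phage with bacteria, PFU/mL
    moi_label: str = ""
    detection_limit: float | None = None
    replicates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        arrays = {}
        for name in ("bc", "bp_b", "pc", "bp_p"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != t.shape:
                raise InputError(f"series {name} does not share the time grid")
            if np.any(arr < 0):
                raise InputError(f"series {name} has negative concentrations")
            arrays[name] = arr
        object.__setattr__(self, "times_h", t)
        for name, arr in arrays.items():
            object.__setattr__(self, name, arr)


@dataclass(frozen=True)
class RegrowthResult:
    regrowth: bool
    onset_h: float | None
    magnitude_log: float
    method: str = "threshold"


@dataclass(frozen=True)
class ReductionProfile:
    times_h: np.ndarray
    reduction_log: np.ndarray  # log10(BC) - log10(BP-B)
    censored: np.ndarray  # True where BP-B was below detection (">=")
    max_reduction: float
    time_of_max_h: float
    regrowth: RegrowthResult


def log_reduction(
    kc: KillingCurveSet,
    min_rise_log: float = 0.5,
    min_points: int = 2,
) -> ReductionProfile:
    """Per-time log10 reduction of treated bacteria versus the control.

    Where the treated series is censored at the detection limit, the
    reduction is computed against the limit and flagged as a lower
    bound (a ">=" value).
    """
    bc, bp = kc.bc, kc.bp_b
    if np.any(bc <= 0):
        raise InputError("bacterial control must be positive wherever compared")
    censored = np.zeros_like(bc, dtype=bool)
    treated = bp.copy()
    if kc.detection_limit is not None:
        censored = treated < kc.detection_limit
        treated = np.where(censored, kc.detection_limit, treated)
    elif np.any(treated <= 0):
        raise InputError(
            "treated series hits zero; supply detection_limit for censored handling"
        )
    reduction = np.log10(bc) - np.log10(treated)
    i_max = int(np.argmax(reduction))
    regrowth = detect_regrowth(
        kc.times_h, np.log10(treated), min_rise_log=min_rise_log, min_points=min_points
    )
    return ReductionProfile(
        times_h=kc.times_h,
        reduction_log=reduction,
        censored=censored,
        max_reduction=float(reduction[i_max]),
        time_of_max_h=float(kc.times_h[i_max]),
        regrowth=regrowth,
    )


def phage_amplification(kc: KillingCurveSet) -> dict:
    """Log10 PFU gain of the co-incubated phage series.

    Reports the gain over the series' own t=0 baseline and the gain
    over the cell-free phage control at each time, plus the maximum
    baseline gain and when it occurred.
    """
    if kc.bp_p[0] <= 0:
        raise InputError("phage series needs a positive t=0 baseline")
    if np.any(kc.bp_p <= 0) or np.any(kc.pc <= 0):
        raise InputError("phage series must be positive for log gains")
    gain_baseline = np.log10(kc.bp_p) - np.log10(kc.bp_p[0])
    gain_over_pc = np.log10(kc.bp_p) - np.log10(kc.pc)
    i_max = int(np.argmax(gain_baseline))
    return {
        "times_h": kc.times_h,
        "gain_over_baseline_log": gain_baseline,
        "gain_over_pc_log": gain_over_pc,
        "max_gain_log": float(gain_baseline[i_max]),
        "time_of_max_h": float(kc.times_h[i_max]),
    }


def detect_regrowth(
    times_h,
    log_series,
    min_rise_log: float = 0.5,
    min_points: int = 2,
) -> RegrowthResult:
    """Threshold-and-persistence regrowth rule on a log10 series.

    Regrowth is declared when the series rises at least ``min_rise_log``
    above its running minimum and stays that far above for at least
    ``min_points`` consecutive samples; the onset is the first time of
    the first qualifying run.  A rise counts only after the series has
    actually declined below its starting level — initial growth of an
    untreated-looking series is growth, not regrowth.
    """
    t = np.asarray(times_h, dtype=float)
    y = np.asarray(log_series, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise InputError("times and series must be parallel 1-D arrays")
    if t.size < 4:
        raise NotApplicableError("regrowth detection needs at least 4 time points")
    running_min = np.minimum.accumulate(y)
    rise = y - running_min
    above = (rise >= min_rise_log) & (running_min < y[0])
    run = 0
    for i, flag in enumerate(above):
        run = run + 1 if flag else 0
        if run >= min_points:
            onset_idx = i - run + 1
            return RegrowthResult(
                regrowth=True,
                onset_h=float(t[onset_idx]),
                magnitude_log=float(rise[onset_idx:].max()),
            )
    # a qualifying run truncated by the end of the series still counts
    # only if it already spans min_points samples, handled above
    return RegrowthResult(regrowth=False, onset_h=None, magnitude_log=float(rise.max()))


def detect_regrowth_replicates(
    times_h,
    log_replicates,
    alpha: float = 0.05,
    min_points: int = 2,
) -> RegrowthResult:
    """Replicate-aware regrowth test.

    Finds the running-minimum time of the mean series and compares each
    later time point against it with a one-sided Welch t-test; regrowth
    is declared on ``min_points`` consecutive significant rises.
    """
    t = np.asarray(times_h, dtype=float)
    reps = np.asarray(log_replicates, dtype=float)
    if reps.ndim != 2 or reps.shape[0] != t.size:
        raise InputError("replicates must be (n_times, n_reps)")
    if reps.shape[1] < 2:
        raise NotApplicableError("Welch comparison needs >= 2 replicates")
    if t.size < 4:
        raise NotApplicableError("regrowth detection needs at least 4 time points")
    mean = reps.mean(axis=1)
    i_min = int(np.argmin(mean))
    baseline = reps[i_min]
    run = 0
    for i in range(i_min + 1, t.size):
        res = stats.ttest_ind(reps[i], baseline, equal_var=False, alternative="greater")
        significant = res.pvalue < alpha
        run = run + 1 if significant else 0
        if run >= min_points:
            onset_idx = i - run + 1
            return RegrowthResult(
                regrowth=True,
                onset_h=float(t[onset_idx]),
                magnitude_log=float((mean[onset_idx:] - mean[i_min]).max()),
                method="welch",
            )
    return RegrowthResult(
        regrowth=False,
        onset_h=None,
        magnitude_log=float((mean - mean[i_min]).max()),
        method="welch",
    )


def read_killcurve_csv(path, detection_limit: float | None = None) -> KillingCurveSet:
    """Read a killing-curve table with columns time_h, series, rep, value.

    ``series`` must be one of bc, bp_b, pc, bp_p.  Mean series are
    computed over replicates; raw replicates are retained.
    """
    df = pd.read_csv(path, comment="#")
    required = {"time_h", "series", "value"}
    if required - set(df.columns):
        raise InputError("killing-curve table needs time_h, series, rep, value columns")
    names = ("bc", "bp_b", "pc", "bp_p")
    unknown = set(df["series"].unique()) - set(names)
    if unknown:
        raise InputError(f"unknown series labels: {sorted(unknown)}")
    times = np.unique(df["time_h"].to_numpy(dtype=float))
    means: dict[str, np.ndarray] = {}
    replicates: dict[str, np.ndarray] = {}
    for name in names:
        sub = df[df["series"] == name]
        if sub.empty:
            raise InputError(f"series {name} missing from table")
        grouped = sub.groupby("time_h")["value"]
        if not np.array_equal(np.array(sorted(grouped.groups)), times):
            raise InputError(f"series {name} does not share the common time grid")
        means[name] = grouped.mean().to_numpy(dtype=float)
        counts = grouped.count()
        if counts.nunique() == 1 and counts.iloc[0] > 1:
            replicates[name] = np.vstack(
                [sub[sub["time_h"] == tt]["value"].to_numpy(dtype=float) for tt in times]
            )
    return KillingCurveSet(
        times_h=times,
        bc=means["bc"],
        bp_b=means["bp_b"],
        pc=means["pc"],
        bp_p=means["bp_p"],
        detection_limit=detection_limit,
        replicates=replicates,
    )
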