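"""Counting-based quantitation: drop-plate titers, MOI, virion doses, EOP.

All concentrations are particles per millilitre (PFU/mL for phage,
CFU/mL for bacteria).  Titers are estimated from replicate small-droplet
counts of a serially diluted sample (drop-plate method): the mean count
per droplet, divided by the droplet volume and multiplied by the
dilution factor, estimates the concentration of the undiluted sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError

DEFAULT_DROPLET_VOLUME_ML = 0.005  # 5 microlitre droplets

__all__ = [
    "DropletCounts",
    "TiterEstimate",
    "EopThresholds",
    "EopResult",
    "titer_from_droplets",
    "moi",
    "virion_dose",
    "eop",
    "read_droplet_counts_csv",
]


@dataclass(frozen=True)
class DropletCounts:
    """Plaque or colony counts from replicate droplets of one dilution.

    Parameters
    ----------
    counts
        Non-negative integer counts, one per plated droplet.
    droplet_volume_ml
        Volume of each droplet in mL (default 0.005 mL, i.e. 5 µL).
    dilution_factor
        Fold-dilution of the plated sample relative to the original
        (1e5 means the sample was diluted 10^-5 before plating).
    """

    counts: tuple[int, ...]
    droplet_volume_ml: float = DEFAULT_DROPLET_VOLUME_ML
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        if len(self.counts) == 0:
            raise InputError("droplet counts must be non-empty")
        arr = np.asarray(self.counts)
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise InputError("droplet counts must be integers")
        if np.any(arr < 0):
            raise InputError("droplet counts must be non-negative")
        if not self.droplet_volume_ml > 0:
            raise InputError("droplet_volume_ml must be positive")
        if not self.dilution_factor >= 1:
            raise InputError("dilution_factor must be >= 1")


@dataclass(frozen=True)
class TiterEstimate:
    """A titer in particles/mL with drop-plate provenance.

    ``below_detection`` is set when every droplet count was zero; the
    estimate is then 0 and ``detection_limit`` carries the concentration
    corresponding to a single plaque across all plated droplets, i.e.
    an upper bound on the true titer.
    """

    value: float
    kind: str  # "phage" | "bacteria"
    n_droplets: int
    below_detection: bool = False
    detection_limit: float | None = None

    def __post_init__(self) -> None:
        if self.value < 0:
            raise InputError("titer cannot be negative")
        if self.kind not in ("phage", "bacteria"):
            raise InputError(f"unknown titer kind {self.kind!r}")


def titer_from_droplets(d: DropletCounts, kind: str = "phage") -> TiterEstimate:
    """Estimate a titer from replicate droplet counts.

    value = mean(counts) / droplet_volume_ml * dilution_factor
    """
    mean_count = float(np.mean(d.counts))
    value = mean_count / d.droplet_volume_ml * d.dilution_factor
    below = mean_count == 0
    limit = None
    if below:
        # one plaque over all plated droplets would have been seen
        limit = d.dilution_factor / (d.droplet_volume_ml * len(d.counts))
    return TiterEstimate(
        value=value,
        kind=kind,
        n_droplets=len(d.counts),
        below_detection=below,
        detection_limit=limit,
    )


def moi(phage_titer: float, bacterial_density: float) -> float:
    """Multiplicity of infection: phage particles per bacterial cell."""
    if bacterial_density <= 0:
        raise InputError("bacterial density must be positive for an MOI")
    if phage_titer < 0:
        raise InputError("phage titer cannot be negative")
    return phage_titer / bacterial_density


def virion_dose(titer: float, volume_ml: float) -> float:
    """Total virion count delivered in ``volume_ml`` of a suspension."""
    if titer < 0 or volume_ml < 0:
        raise InputError("titer and volume must be non-negative")
    return titer * volume_ml


@dataclass(frozen=True)
class EopThresholds:
    """Percentage cut-offs for the qualitative EOP score.

    high: EOP >= ``high`` %; medium: ``medium`` <= EOP < ``high``;
    low: ``low`` <= EOP < ``medium``; inefficient: 0 < EOP < ``low``;
    no_lysis: EOP == 0.
    """

    high: float = 50.0
    medium: float = 10.0
    low: float = 0.1

    def __post_init__(self) -> None:
        if not (0 < self.low < self.medium < self.high):
            raise InputError("EOP thresholds must satisfy 0 < low < medium < high")

    def score(self, eop_percent: float) -> str:
        if eop_percent == 0:
            return "no_lysis"
        if eop_percent >= self.high:
            return "high"
        if eop_percent >= self.medium:
            return "medium"
        if eop_percent >= self.low:
            return "low"
        return "inefficient"


@dataclass(frozen=True)
class EopResult:
    eop_percent: float
    score: str
    target_mean_pfu: float
    host_mean_pfu: float
    thresholds: EopThresholds = field(default_factory=EopThresholds)


def eop(
    target_mean_pfu: float,
    host_mean_pfu: float,
    thresholds: EopThresholds | None = None,
) -> EopResult:
    """Efficiency of plating of a phage on a target strain.

    EOP(%) = 100 * (mean PFU on target strain) / (mean PFU on host strain),
    with 100% by construction for the isolation host against itself.
    """
    if host_mean_pfu <= 0:
        raise InputError("host mean PFU must be positive")
    if target_mean_pfu < 0:
        raise InputError("target mean PFU cannot be negative")
    thresholds = thresholds or EopThresholds()
    pct = target_mean_pfu / host_mean_pfu * 100.0
    return EopResult(
        eop_percent=pct,
        score=thresholds.score(pct),
        target_mean_pfu=target_mean_pfu,
        host_mean_pfu=host_mean_pfu,
        thresholds=thresholds,
    )


def read_droplet_counts_csv(path) -> dict[str, DropletCounts]:
    """Read a drop-plate count table.

    Expected columns: ``sample_id``, ``dilution_factor``,
    ``droplet_volume_ml``, then ``count_1`` .. ``count_k``.  Lines
    starting with '#' are treated as comments.
    """
    df = pd.read_csv(path, comment="#")
    required = {"sample_id", "dilution_factor", "droplet_volume_ml"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"missing columns in droplet-count table: {sorted(missing)}")
    count_cols = [c for c in df.columns if c.startswith("count_")]
    if not count_cols:
        raise InputError("no count_* columns in droplet-count table")
    out: dict[str, DropletCounts] = {}
    for _, row in df.iterrows():
        counts = tuple(
            int(row[c]) for c in count_cols if pd.notna(row[c])
        )
        out[str(row["sample_id"])] = DropletCounts(
            counts=counts,
            droplet_volume_ml=float(row["droplet_volume_ml"]),
            dilution_factor=float(row["dilution_factor"]),
        )
    return out
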