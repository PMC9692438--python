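"""Seeded generators for every input the analysis modules consume.

Each generator inverts the model its fitting module estimates (4-PL
growth, reversible adsorption, Beer-Lambert, exponential decay) with a
noise model matching how the quantity is measured: additive Gaussian on
log10 titers, multiplicative lognormal on fractions and areas, Poisson
on droplet counts.  In the zero-noise limit every generator/fitter pair
is an exact inverse.

The co-culture simulator produces structurally realistic killing-curve
fixtures (decline of the treated bacteria after the latent period, then
regrowth from phage-resistant mutants) from a small mechanistic model:
logistic host growth, mass-action adsorption, a fixed latent delay
before burst, and one-way mutation of susceptible to resistant cells.
It is a fixture generator, not an attempt to reproduce any particular
experimental figure.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .adsorption import DEFAULT_ADSORPTION_TIMES_MIN, AdsorptionCurve, adsorption_model
from .errors import InputError
from .genome import GenomeRecord
from .growth import DEFAULT_OSGC_TIMES_MIN, GrowthCurve, four_pl
from .inactivation import KillingCurveSet
from .photometry import DilutionSeries, StorageSeries
from .quantitation import DropletCounts

__all__ = [
    "SimulationConfig",
    "CocultureParams",
    "gen_osgc",
    "gen_adsorption",
    "simulate_coculture",
    "gen_dilution_series",
    "gen_storage",
    "gen_plate_counts",
    "gen_genome",
]

# default generating truths: point estimates in the regime of the two
# characterized coliphages (burst sizes 106 and 10 PFU/cell, latent
# periods 40 and 48 min, adsorption rate ~1.9e-10 mL/CFU/min)
DEFAULT_4PL_TRUTH = {"p0": 4.0, "p_inf": 4.0 + np.log10(106), "a": 30.0, "b": 8.0}
DEFAULT_ADSORPTION_TRUTH = {"delta": 1.904e-10, "phi": 5.664e-3, "x0": 1.0e8}
DEFAULT_STORAGE_DAYS = np.arange(0.0, 46.0, 7.5)  # ~weekly sampling over 45 d


def gen_osgc(
    p0: float,
    p_inf: float,
    a: float,
    b: float,
    times=None,
    noise_sd: float = 0.05,
    n_reps: int = 3,
    rng=None,
) -> GrowthCurve:
    """One-step growth curve: replicate log10 titers on the 4-PL curve."""
    if noise_sd < 0:
        raise InputError("noise_sd must be non-negative")
    rng = np.random.default_rng(rng)
    times = DEFAULT_OSGC_TIMES_MIN if times is None else np.asarray(times, dtype=float)
    t_long = np.repeat(times, n_reps)
    truth = np.asarray(four_pl(t_long, p0, p_inf, a, b))
    y = truth + noise_sd * rng.standard_normal(t_long.size)
    return GrowthCurve(times_min=t_long, log_titers=y)


def gen_adsorption(
    delta: float,
    phi: float,
    x0: float,
    times=None,
    noise_sd: float = 0.1,
    n_reps: int = 3,
    rng=None,
) -> AdsorptionCurve:
    """Free-phage fractions from the reversible-adsorption closed form.

    Noise is multiplicative lognormal with the given log-scale sd,
    matching titer-ratio measurement error; t=0 is always present.
    """
    if noise_sd < 0:
        raise InputError("noise_sd must be non-negative")
    rng = np.random.default_rng(rng)
    times = (
        DEFAULT_ADSORPTION_TIMES_MIN if times is None else np.asarray(times, dtype=float)
    )
    if 0.0 not in times:
        times = np.concatenate([[0.0], times])
    t_long = np.repeat(times, n_reps)
    truth = np.asarray(adsorption_model(t_long, delta, phi, x0))
    if noise_sd > 0:
        frac = truth * rng.lognormal(0.0, noise_sd, size=t_long.size)
    else:
        frac = truth
    frac = np.clip(frac, 0.0, 1.2)
    return AdsorptionCurve(times_min=t_long, free_fraction=frac, x0=x0)


@dataclass(frozen=True)
class CocultureParams:
    """Mechanistic parameters for the phage-bacteria co-culture model.

    Defaults place the simulation in the regime of an exponentially
    growing *E. coli* culture (doubling time ~30 min) challenged at
    MOI 1 with a phage of burst size 106 and latent period 40 min.
    """

    growth_rate_per_h: float = 1.4
    carrying_capacity_per_ml: float = 1.0e9
    delta_ml_per_cfu_min: float = 1.904e-10
    latent_period_min: float = 40.0
    burst_size: float = 106.0
    mutation_prob: float = 1e-7  # resistance mutations per division
    s0_per_ml: float = 1.0e5
    p0_per_ml: float = 1.0e5  # MOI 1 against s0
    volume_ml: float = 10.0

    def __post_init__(self) -> None:
        vals = asdict(self)
        if any(v < 0 for v in vals.values()):
            raise InputError("co-culture parameters must be non-negative")
        if not self.carrying_capacity_per_ml > self.s0_per_ml:
            raise InputError("carrying capacity must exceed the initial density")
        if not 0 <= self.mutation_prob <= 1:
            raise InputError("mutation_prob must be a probability")


def _integrate_coculture(
    p: CocultureParams,
    horizon_h: float,
    dt_h: float,
    stochastic: bool,
    rng,
    s0: float,
    p0: float,
):
    """Forward-integrate one run; returns (times_h, S+R, P, bookkeeping)."""
    n_steps = int(round(horizon_h / dt_h))
    latent_steps = max(int(round(p.latent_period_min / 60.0 / dt_h)), 1)
    V = p.volume_ml
    delta_h = p.delta_ml_per_cfu_min * 60.0  # mL CFU^-1 h^-1
    K = p.carrying_capacity_per_ml * V

    S = s0 * V
    R = 0.0
    P = p0 * V
    queue = np.zeros(n_steps + latent_steps + 1)
    total_adsorbed = 0.0
    total_bursts = 0.0

    times = np.empty(n_steps + 1)
    cells = np.empty(n_steps + 1)
    phage = np.empty(n_steps + 1)
    infected = np.empty(n_steps + 1)
    times[0], cells[0], phage[0], infected[0] = 0.0, S + R, P, 0.0
    pending = 0.0

    for k in range(n_steps):
        N = S + R + pending
        g = max(0.0, 1.0 - N / K)
        div_s_mean = p.growth_rate_per_h * S * g * dt_h
        div_r_mean = p.growth_rate_per_h * R * g * dt_h
        # adsorption hazard per phage over this step
        hazard = delta_h * (S / V) * dt_h
        ads_mean = P * (1.0 - np.exp(-hazard)) if hazard > 0 else 0.0
        if stochastic:
            div_s = rng.poisson(div_s_mean)
            div_r = rng.poisson(div_r_mean)
            mut = rng.binomial(div_s, p.mutation_prob) if div_s > 0 else 0
            ads = min(float(rng.poisson(ads_mean)), S + div_s - mut, P)
        else:
            div_s = div_s_mean
            div_r = div_r_mean
            mut = div_s * p.mutation_prob
            ads = min(ads_mean, S + div_s - mut, P)
        bursting = queue[k]
        S = S + div_s - mut - ads
        R = R + div_r + mut
        P = P - ads + p.burst_size * bursting
        queue[k + latent_steps] += ads
        pending = pending + ads - bursting
        total_adsorbed += ads
        total_bursts += bursting
        if S < 0 or R < 0 or P < 0:
            raise InputError("state went negative; decrease dt_h")
        times[k + 1] = (k + 1) * dt_h
        cells[k + 1] = S + R
        phage[k + 1] = P
        infected[k + 1] = pending

    bookkeeping = {
        "p0_total": p0 * V,
        "p_final": P,
        "total_adsorbed": total_adsorbed,
        "total_bursts": total_bursts,
        "pending_infections": pending,
    }
    return times, cells / V, phage / V, bookkeeping


def simulate_coculture(
    p: CocultureParams | None = None,
    horizon_h: float = 24.0,
    dt_h: float = 1.0 / 120.0,
    stochastic: bool = False,
    rng=None,
    output_times_h=None,
    detection_limit: float = 200.0,
) -> tuple[KillingCurveSet, dict]:
    """Simulate BC, PC and BP runs of a killing-curve experiment.

    Three runs share parameters and grid: the bacterial control (no
    phage), the phage control (no bacteria) and the co-culture.  The
    returned set carries mean concentration series sampled at
    ``output_times_h`` (default 0,2,...,12,24 h) plus a bookkeeping
    dict for phage-conservation checks on the co-culture run:
    P(t) = P(0) - adsorbed + burst_size * completed_bursts.
    """
    p = p or CocultureParams()
    if dt_h <= 0 or horizon_h < dt_h:
        raise InputError("need 0 < dt_h <= horizon_h")
    if p.latent_period_min / 60.0 < 4 * dt_h:
        raise InputError("dt_h too coarse relative to the latent period")
    rng = np.random.default_rng(rng)
    if output_times_h is None:
        output_times_h = np.array([0.0, 2, 4, 6, 8, 10, 12, 24])
    output_times_h = np.asarray(output_times_h, dtype=float)
    if output_times_h.max() > horizon_h:
        raise InputError("output times exceed the simulation horizon")

    t, bp_cells, bp_phage, book = _integrate_coculture(
        p, horizon_h, dt_h, stochastic, rng, s0=p.s0_per_ml, p0=p.p0_per_ml
    )
    _, bc_cells, _, _ = _integrate_coculture(
        p, horizon_h, dt_h, stochastic, rng, s0=p.s0_per_ml, p0=0.0
    )
    _, _, pc_phage, _ = _integrate_coculture(
        p, horizon_h, dt_h, stochastic, rng, s0=0.0, p0=p.p0_per_ml
    )

    idx = np.searchsorted(np.round(t, 12), np.round(output_times_h, 12))
    kc = KillingCurveSet(
        times_h=output_times_h,
        bc=bc_cells[idx],
        bp_b=bp_cells[idx],
        pc=pc_phage[idx],
        bp_p=bp_phage[idx],
        moi_label=f"MOI {p.p0_per_ml / p.s0_per_ml:g}" if p.s0_per_ml else "",
        detection_limit=detection_limit,
    )
    return kc, book


def gen_dilution_series(
    epsilon: float,
    concentrations=None,
    noise_sd: float = 0.0,
    intercept: float = 0.0,
    scatter_a320: float = 0.05,
    path_length_cm: float = 1.0,
    rng=None,
) -> DilutionSeries:
    """Beer-Lambert dilution series with Gaussian absorbance noise.

    The raw 255 nm reading includes a flat scattering offset that the
    320 nm channel measures, so corrected absorbance recovers
    epsilon * c + intercept (+ noise).
    """
    rng = np.random.default_rng(rng)
    if concentrations is None:
        concentrations = np.array([0.5e9, 1e9, 1.5e9, 2e9, 2.5e9, 3e9])
    c = np.asarray(concentrations, dtype=float)
    a320 = np.full(c.size, scatter_a320)
    a255 = epsilon * c * path_length_cm + intercept + a320
    if noise_sd > 0:
        a255 = a255 + noise_sd * rng.standard_normal(c.size)
        a255 = np.clip(a255, 0.0, None)
    return DilutionSeries(
        concentrations=c, a255=a255, a320=a320, path_length_cm=path_length_cm
    )


def gen_storage(
    tau_days: float,
    days=None,
    noise_sd: float = 0.0,
    rng=None,
) -> StorageSeries:
    """Normalized lytic-area decay exp(-t/tau) with lognormal noise."""
    rng = np.random.default_rng(rng)
    days = DEFAULT_STORAGE_DAYS if days is None else np.asarray(days, dtype=float)
    ratios = np.exp(-days / tau_days)
    if noise_sd > 0:
        noise = rng.lognormal(0.0, noise_sd, size=days.size)
        noise[days == 0] = 1.0  # normalization anchor stays exact
        ratios = ratios * noise
    return StorageSeries(days=days, ratios=ratios)


def gen_plate_counts(
    titer: float,
    droplet_volume_ml: float = 0.005,
    dilution_factor: float = 1e5,
    n_droplets: int = 3,
    rng=None,
) -> DropletCounts:
    """Poisson droplet counts with mean titer * volume / dilution."""
    rng = np.random.default_rng(rng)
    lam = titer * droplet_volume_ml / dilution_factor
    counts = tuple(int(c) for c in rng.poisson(lam, size=n_droplets))
    return DropletCounts(
        counts=counts,
        droplet_volume_ml=droplet_volume_ml,
        dilution_factor=dilution_factor,
    )


def gen_genome(
    length: int,
    gc: float = 0.45,
    skew: float = 0.0,
    identifier: str = "synthetic",
    circular: bool = False,
    rng=None,
) -> GenomeRecord:
    """Random genome with i.i.d. bases at the target GC fraction.

    With nonzero ``skew`` the first half over-represents G and the
    second half over-represents C by the same amount (each half's
    expected windowed skew is +/- ``skew``), giving a two-phase profile
    like the origin/terminus structure of circular genomes.
    """
    if not 0 <= gc <= 1 or not -1 <= skew <= 1:
        raise InputError("need 0 <= gc <= 1 and -1 <= skew <= 1")
    rng = np.random.default_rng(rng)
    half = length // 2
    g_hi, g_lo = gc / 2 * (1 + skew), gc / 2 * (1 - skew)
    at = (1 - gc) / 2
    first = rng.choice(list("GCAT"), size=half, p=[g_hi, g_lo, at, at])
    second = rng.choice(list("GCAT"), size=length - half, p=[g_lo, g_hi, at, at])
    seq = "".join(first) + "".join(second)
    return GenomeRecord(identifier=identifier, sequence=seq, circular=circular)


@dataclass
class SimulationConfig:
    """Seeded configuration bundle for the ``simulate`` CLI command."""

    seed: int = 0
    osgc: dict = field(default_factory=lambda: dict(DEFAULT_4PL_TRUTH, noise_sd=0.05, n_reps=3))
    adsorption: dict = field(
        default_factory=lambda: dict(DEFAULT_ADSORPTION_TRUTH, noise_sd=0.1, n_reps=3)
    )
    coculture: dict = field(default_factory=dict)
    dilution: dict = field(default_factory=lambda: {"epsilon": 2.994e-10, "noise_sd": 0.0})
    storage: dict = field(default_factory=lambda: {"tau_days": 11.494, "noise_sd": 0.0})
    plate_counts: dict = field(default_factory=lambda: {"titer": 4.0e8})
    genome: dict = field(default_factory=lambda: {"length": 10000, "gc": 0.45})

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        base = cls()
        for key, value in raw.items():
            if isinstance(value, dict):
                merged = dict(getattr(base, key))
                merged.update(value)
                setattr(base, key, merged)
            else:
                setattr(base, key, value)
        return base

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def rng(self):
        return np.random.default_rng(self.seed)
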