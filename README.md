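# phagekit

Quantitative analyses for characterizing lytic bacteriophages as
antibacterial agents — written for microbiologists who isolate a phage
against a clinical pathogen (the motivating case is *E. coli* pyometra
in dogs) and need the numbers that decide whether it is therapeutically
useful: titers, host range, growth parameters, adsorption rates,
killing-curve reductions, UV-based quantification, and formulation
shelf life.

## What it computes

**Titers, MOI, doses, EOP** (`phagekit.quantitation`). Drop-plate
titers `mean(count) / V_droplet × dilution`, multiplicity of infection
`PFU/CFU`, virion doses `titer × volume`, and efficiency of plating
`EOP(%) = 100 × PFU_target / PFU_host` with a configurable
high/medium/low/inefficient score.

**One-step growth curves** (`phagekit.growth`). Log-titer time courses
are fitted to the 4-parameter logistic

&nbsp;&nbsp;&nbsp;&nbsp;log₁₀ P(t) = P∞ + (P₀ − P∞) / (1 + (t/A)^B)

by least squares; the eclipse and latent periods are the times at which
the fitted curve completes fractions f_lo = 0.05 and f_hi = 0.95 of its
rise, t(f) = A·(f/(1−f))^(1/B), the intracellular accumulation period
is their difference, and the burst size is 10^(P∞ − P₀).

**Reversible adsorption kinetics** (`phagekit.adsorption`). Free-phage
fractions follow

&nbsp;&nbsp;&nbsp;&nbsp;P(t)/P₀ = (ϕ + δX₀·e^{−(δX₀+ϕ)t}) / (δX₀ + ϕ)

where δ (mL·CFU⁻¹·min⁻¹) is the mass-action adsorption rate onto host
cells at density X₀ and ϕ (min⁻¹) the desorption rate from the
reversible phage–bacterium complex; both are estimated by bounded least
squares.

**Goodness of fit** (`phagekit.fitstats`). Replicated lack-of-fit
F-test (pure-error vs lack-of-fit SS decomposition), r², and
delta-method or bootstrap confidence bands for any fitted curve.

**Killing curves** (`phagekit.inactivation`). Per-time log₁₀
reductions of treated bacteria versus the untreated control (with
detection-limit censoring), phage amplification over baseline and over
the cell-free control, and regrowth detection by a
threshold-and-persistence rule or replicate-aware Welch comparisons.

**UV calibration and storage decay** (`phagekit.photometry`).
Scattering-corrected absorbance A₂₅₅ − A₃₂₀ fitted to Beer–Lambert
A = ε·c·l for a particle-count extinction coefficient ε, its inverse
for titer-from-absorbance, and exponential shelf-life decay
A(t)/A(0) = e^{−t/τ} with decay rate λ = 1/τ.

**Genome summaries** (`phagekit.genome`). FASTA parsing, length, GC
content (N excluded from the denominator), and windowed GC skew
(G−C)/(G+C) with circular wrap-around.

**Synthetic data** (`phagekit.synthetic`). Seeded generators inverting
each model above, plus a mechanistic phage–bacteria co-culture
simulator (logistic host growth, mass-action adsorption, fixed latent
delay, burst, and one-way resistance mutation) that produces realistic
decline-then-regrowth killing curves.

## Worked example

```python
import numpy as np
from phagekit.growth import fit_4pl, extract_growth_parameters
from phagekit.adsorption import fit_adsorption, adsorbed_percent, adsorption_model
from phagekit.synthetic import gen_osgc, gen_adsorption

# one-step growth curve, 3 replicates, noise sd 0.05 log units
curve = gen_osgc(p0=4.0, p_inf=4.0 + np.log10(106), a=30.0, b=8.0,
                 noise_sd=0.05, n_reps=3, rng=1)
gp = extract_growth_parameters(fit_4pl(curve))
print(f"eclipse {gp.eclipse_min:.1f} min, latent {gp.latent_min:.1f} min, "
      f"burst {gp.burst_size:.0f} PFU/cell")

# adsorption curve at host density 1e8 CFU/mL
ads = fit_adsorption(gen_adsorption(delta=1.904e-10, phi=5.664e-3, x0=1.0e8,
                                    noise_sd=0.0))
print(f"delta {ads.delta:.3e} mL/CFU/min, phi {ads.phi:.3e} /min, "
      f"adsorbed at 150 min {adsorbed_percent(ads.predict(150.0)):.1f}%")
```

prints

```
eclipse 20.8 min, latent 43.5 min, burst 104 PFU/cell
delta 1.904e-10 mL/CFU/min, phi 5.664e-03 /min, adsorbed at 150 min 75.2%
```

The eclipse/latent times are the 5%/95% rise-crossing times of the
fitted sigmoid; the burst size is the plateau-to-baseline titer ratio,
here recovered within 2% of the generating value 106 despite the
replicate noise; the noise-free adsorption fit recovers the generating
rates exactly and predicts that about three quarters of virions are
cell-bound after 150 min.

The same analyses are available from a shell via the `phagekit` CLI
(`simulate`, `titer`, `eop`, `fit-osgc`, `fit-adsorption`, `lackfit`,
`killcurve`, `extinction`, `storage-decay`, `genome-stats`), each
emitting a deterministic JSON report.

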