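# Methods

This note documents the models phagekit implements, the defaults it
ships, the numerical choices behind the fits, and what the synthetic
generators do and do not emulate.

## Drop-plate quantitation

A titer is estimated from k replicate droplets of one dilution as
`mean(count) / V_droplet × dilution_factor` (default droplet volume
0.005 mL, i.e. 5 µL). When every droplet reads zero, the estimate is 0
and a `below_detection` flag carries the limit
`dilution_factor / (V_droplet × k)` — the concentration at which a
single plaque would have appeared across all plated droplets. This
censoring information feeds the killing-curve log reductions, which
report "≥" bounds at censored points instead of infinities.

EOP is the percentage ratio of mean plaque counts on a target strain
versus the isolation host; the host against itself is exactly 100% by
construction. The qualitative score uses the common convention
high ≥ 50%, medium ≥ 10%, low ≥ 0.1%, inefficient below that and
no_lysis at zero; the thresholds are a frozen dataclass the caller can
replace, because published scoring conventions vary and none is
printed alongside most EOP tables.

## One-step growth curves

The 4-PL model `log10 P(t) = p_inf + (p0 − p_inf)/(1 + (t/a)^b)` is
fitted to log10 titers — not raw titers — because replicate titer noise
is approximately multiplicative, making log-scale least squares the
natural error model. Fitting uses `scipy.optimize.least_squares`
(trust-region reflective, bounds a, b > 0) initialized from the data:
p0/p_inf from the min/max group means, a from the first time the group
means cross the midpoint, b = 5; up to 3 restarts from jittered
initial values if the optimizer reports failure. Tolerances are
1e-14 on step/cost; a degenerate-fit error is raised when the group
means span less than 1e-3 log units (both configurable).

Growth parameters are read off the fitted curve as rise-fraction
crossing times, t(f) = a·(f/(1−f))^(1/b): eclipse at f_lo = 0.05,
latent at f_hi = 0.95, accumulation = latent − eclipse, and burst size
10^(p_inf − p0). The fraction convention is a package choice — the
crossing times are exactly computable from the fit, reproduce the
expected ordering eclipse < latent, and with symmetric fractions
(f_lo = 1 − f_hi) satisfy eclipse·latent = a², which the tests assert.
The classical chloroform-assisted eclipse determination is out of
scope; the fit-only convention is recorded in the output metadata.
Burst size as the plateau-to-baseline ratio assumes every input phage
productively infected a cell, which the low-MOI synchronized design
approximates.

## Reversible adsorption kinetics

Free phage P and susceptible cells at fixed density X0 exchange with a
reversible complex at mass-action rate δ·X0 and first-order release
rate ϕ, giving `P(t)/P0 = (ϕ + δX0·e^{−(δX0+ϕ)t})/(δX0 + ϕ)`. Internal
units are minutes throughout: δ in mL·CFU⁻¹·min⁻¹ (δ·X0 in min⁻¹) and
ϕ in min⁻¹, consistent with the 150-min span of the standard assay; an
hour-based reading of either rate is a ×60 rescale the caller can
apply. The default sampling grid is 5-min intervals to 30 min then
10-min intervals to 150 min (19 points), the standard design for this
assay.

The fit is bounded least squares on (δ, ϕ) with X0 known and fixed.
Initial guesses come from the observed half-decay time
(δ0 = ln2/(X0·t_half), ϕ0 = 0.1·δ0·X0); tolerances are 1e-12 with a
5000-evaluation budget (tighter tolerances make the trust-region
solver exhaust its budget in flat directions of the (δ, ϕ) landscape
without improving the optimum). A curve that never leaves 1 fits to
δ ≈ 0 with equilibrium free fraction 1 and is flagged `no_adsorption`.

## Lack of fit, r², confidence bands

With n observations at m distinct design points and a p-parameter
model, the residual SS about the fitted curve decomposes into pure
error (within replicate groups, df n − m) and lack of fit (group means
about fitted values, df m − p); their mean-square ratio is referred to
F(m−p, n−m). The test consumes an already-fitted model — it never
re-estimates inside — and degenerates gracefully: zero pure error
(identical replicates) flags the F as undefined rather than dividing
by zero. α defaults to 0.05.

Confidence bands default to the delta method (numerical Jacobian of
the prediction function propagated through the parameter covariance,
normal quantile unless a df is supplied); a seeded percentile bootstrap
with 199 residual resamples is the fallback when the covariance is
singular, and requires the caller to pass a refit callable. The delta
band is deterministic, which is why it is the default.

## Killing curves

Log reduction is `log10 BC(t) − log10 BP-B(t)` on a shared grid, with
censored treated values evaluated at the detection limit and flagged.
Published regrowth assessments typically rely on replicate ANOVA whose
raw data are unavailable to reanalysis, so two operational rules are
provided. For a single mean series: regrowth when the series rises
≥ 0.5 log above its running minimum and stays there ≥ 2 consecutive
samples, with the additional requirement that the running minimum has
dropped below the series' starting level — without it, the initial
growth phase of a treated culture that expands before the phage
overtake it would be misread as regrowth. For replicate input: a
one-sided Welch t-test of each later time against the running-minimum
time at α = 0.05, with the same persistence requirement. Killing-curve
times are hours; growth/adsorption times are minutes; no implicit
conversion is performed.

## Photometry and storage decay

Corrected absorbance is A255 − A320 (the 320 nm channel measures
scattering only); negative corrected values are returned with a
warning rather than clipped, as they indicate contamination worth
seeing. The Beer–Lambert calibration is through-origin by default
(the law has no intercept); a free intercept is available as a
diagnostic. The extinction coefficient is per particle concentration,
(PFU/mL)⁻¹·cm⁻¹.

Storage decay fits `A(t)/A(0) = e^{−t/τ}` by through-origin linear
regression of ln ratio on time — exact for the one-parameter model,
no iteration — with an optional nonlinear refit on the ratio scale.
Non-positive ratios are excluded with a warning. The decay rate
λ = 1/τ and mean lifetime τ are reported as an exactly reciprocal
pair; the package never adjusts one to match an externally rounded
value of the other. A flat series yields τ = ∞, λ = 0 and a
`no_decay` flag.

## Genome summaries

GC fraction is (G+C)/(A+C+G+T) with N excluded from the denominator
and counted separately; the display percentage is rounded to the
nearest integer. GC skew windows are 0-based half-open, reported by
start, wrapping past the sequence end only for records flagged
circular; windows devoid of G and C report NaN. Reverse-complementing
a sequence negates every defined skew value and preserves GC fraction,
which the tests assert.

## Synthetic data and the co-culture simulator

Noise models follow how each quantity is measured: additive Gaussian
on log10 titers (default sd 0.05, 3 replicates), multiplicative
lognormal on free fractions and areas (default log-sd 0.1), Gaussian
on absorbances, Poisson on droplet counts. Default generating
parameters sit in the regime of the two characterized coliphages
(burst sizes 106 and 10, latent periods 40 and 48 min,
δ ≈ 1.9×10⁻¹⁰ mL·CFU⁻¹·min⁻¹, ϕ of a few 10⁻³–10⁻² min⁻¹, X0 = 10⁸
CFU/mL, ε ≈ 3×10⁻¹⁰ (PFU/mL)⁻¹·cm⁻¹, τ ≈ 11.5 d). Storage sampling
defaults to roughly weekly points over 45 days, a typical cold-storage
design. Every generator is an exact right inverse of its fitter at
zero noise, and all outputs are bit-reproducible given a seed.

The co-culture simulator tracks susceptible cells S, resistant cells
R, a latent infected pool and free phage P in absolute counts
(concentration × volume, default 10 mL): logistic growth of S and R at
rate 1.4 h⁻¹ toward carrying capacity 10⁹ CFU/mL (an exponential-phase
*E. coli* culture), mass-action adsorption removing one phage and one
S cell per event, bursts of b phage exactly one latent period after
infection (a discrete delay queue, default 40 min at a 0.5-min step),
and one-way mutation S→R at probability m per division (default
10⁻⁷). Integration is deterministic Euler with exponential-hazard
adsorption updates (which cannot overshoot into negative states), or a
Poisson/binomial tau-leap when stochastic. Phage bookkeeping
P(t) = P(0) − adsorbed + b × completed bursts holds to machine
precision by construction and is asserted to 1e-6 relative. Each
experiment returns three runs on one grid — bacterial control (no
phage), phage control (no cells) and the co-culture — sampled by
default at 0, 2, …, 12, 24 h with a 200 /mL detection limit (one
plaque per 5 µL droplet).

The simulator emulates the *shape* of killing-curve data — initial
growth, post-latent collapse, regrowth from resistant mutants, phage
amplification of ~3 log — not any particular published figure: it
omits phage decay, multiple adsorptions per cell, partial resistance,
spatial structure and host physiology. Passing tests therefore show
that the analysis code measures these motifs correctly, not that the
model predicts real co-cultures quantitatively.

## Problem sizes

All analyses are desk-scale: 19-point curves, 3 replicates, 20-seed
simulation suites, 24-h co-culture horizons at a 0.5-min step
(~2,880 steps per run). The full test suite runs in seconds; the
acceptance script in under five.
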