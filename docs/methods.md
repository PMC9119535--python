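# Methods

## Model

The simulator couples coral abundance *C* (cm² of living coral surface),
symbiont abundance *S* (cells) and a community-mean trait *U* (energy
invested in the symbiosis per cm² per month; the unit is deliberately
abstract — a less abstract formulation would require laboratory carbon
and nitrogen budgets).  Corals grow logistically toward a regional
carrying capacity `K_C` at a rate set by three multiplicative limits:
temperature, symbiont supply, and energy investment; they pay an
investment-dependent symbiotic cost and a small background mortality
`M_C`.  Symbionts grow logistically with capacity `K_S = K_smax·C` —
the host fully controls algal growth, so the symbiont pool is slaved to
the coral surface available to house it.  The trait follows the coral
fitness gradient, `dU/dt = N·∂F/∂U`: the community continuously shifts
its mean investment toward the value that maximises per-capita growth,
and the proportionality constant *N* (the speed of acclimation) is the
one parameter estimated from data.  This is an adaptive-dynamics
formulation of phenotypic plasticity at the community scale: no genetic
change is represented, and in particular the thermal performance curves
are fixed — shifting thermal optima (genetic adaptation) is explicitly
outside the model.

Temperature enters twice.  Coral growth follows a skew-normal occurrence
curve `G(T) = φ(z)·Φ(s·z)` with `z = (T−T̄)/σ`, normalised by its mode so
the rate at the optimum is exactly `G_max`; the mode has no closed form
and is located numerically (coarse 241-point grid over `T̄ ± 6σ`, then
bounded golden-section/parabolic refinement to 1e-3 °C, cached per
parameter triple).  The skewness `s` is treated as a dimensionless shape
parameter: it multiplies the standardised anomaly inside a standard
normal CDF, which is only dimensionally consistent for a dimensionless
`s`, and the Great Barrier Reef value of 2·10⁻⁴ is only sensible on that
reading.  Symbiont growth is the exponential envelope `G_S = a·e^{b·T}`
with no decline at high temperature; heat harms the symbiosis through
bleaching, not through the symbiont growth law.

Bleaching is a discrete stochastic process at the monthly forcing
resolution.  When a month's SST exceeds `T_opt` by a margin inside one of
the region's observed exceedance bands, the symbiont pool is multiplied
by `1 − ρ/100` with ρ drawn uniformly from the band's observed reduction
range.  Two readings of the event trigger were possible; we fire an
event deterministically whenever the realized exceedance enters any band
and let the exceedance itself select the band (the alternative — drawing
a random threshold from the band — adds a second layer of stochasticity
the observations cannot constrain).  At most one event fires per month,
applied as an instantaneous reduction before that month's integration.
A 95 % draw removes 95 % of the cells (the reduction reading; the
retained-fraction reading would make the severest observed events the
mildest).  Because triggers and severities depend only on the forcing,
the whole event sequence is pre-drawn from one isolated seeded stream,
which makes runs reproducible and lets replicate runs share everything
but the bleaching draws.

## Parameters

Cross-region constants (units per month unless noted): `G_max = 0.83`
(maximum coral growth), `a = 0.09`, `b = 0.063 °C⁻¹` (symbiont
envelope), `K_smax = 3·10⁶ cells·cm⁻²`, `M_C = 0.83·10⁻³` (background
mortality), `α = 10⁻³` and `r = 12·10³` (cost scale and steepness),
`β = 12·10²` (benefit saturation), `Γ_h = 10⁶ cells·cm⁻²` (feedback
half-saturation ratio).  Regional presets: GBR (`K_C = 4.4·10¹⁵ cm²`,
`T̄ = T_opt = 26.8 °C`, `σ = 1.0`, `s = 2·10⁻⁴`, `N = 5.54·10⁻¹³`), SEA
(`1.2·10¹⁶`, `T̄ = 28.1`, `T_opt = 28.5`, `σ = 0.8`, `s = 3.8`,
`N = 2.65·10⁻¹³`), CAR (`1.9·10¹⁵`, `T̄ = 27.1`, `T_opt = 27.6`,
`σ = 0.9`, `s = 1.1`, `N = 2.375·10⁻¹³`), with fixed spin-up temperatures
25.90 / 28.45 / 27.57 °C (the regional 1955–2000 means) and the
region-specific bleaching band tables.  All parameter containers are
frozen; perturbation studies operate on copies.

## Numerics

Integration works in nondimensional variables `c = C/K_C`,
`s = S/(K_smax·K_C)` (so the symbiont capacity becomes simply `c`), with
*U* unscaled: *C* and *U* differ by ~22 orders of magnitude and the
scaling keeps the Runge–Kutta arithmetic well conditioned.  The default
integrator is classical RK4 with 10 substeps per month and
piecewise-constant monthly forcing; halving the step changes end-of-run
states by well under 1e-5 relative, and an adaptive LSODA path (rtol
1e-10) exists for verification — the two agree to better than 1e-6 on
forced runs.  The monthly loop is compiled with numba when available;
the pure-Python fallback runs the identical code.  A guard `ε = 10⁻¹²`
(in scaled units, configurable) is added to the denominators `Γ_h·C + S`
and `K_S` to prevent division by zero near `C = 0`.  Negative excursions
from discretisation are clipped to zero and logged; excursions beyond
1e-12 (scaled) abort the run, as does any non-finite state.  The trait
equation uses the closed-form gradient
`∂F/∂U = G_C·κ·(1−C/K_C)·β·e^{−βU} − α·r·e^{rU}·S/K_S`; a
finite-difference gradient exists only as a test oracle and agrees to
better than 1e-6 relative over thousands of random states.  Degenerate
inputs: with `S = 0` the feedback, cost and gradient all vanish and
corals decay at exactly `M_C`; with `C = 0` the guarded capacity drives
any remaining symbionts down instead of dividing by zero.

## Protocol

Runs follow the published experiment design: initial conditions
`C = 0.75·K_C`, `S = 10⁻³` cells, `U = 5·10⁻⁷`; a 2000-year spin-up at
the fixed regional temperature with bleaching off; then the monthly
forced era (1955–2100 in the full design) with bleaching checked each
month before the month's integration.  One property of the published
protocol does not survive quantitative scrutiny: with the published
speeds of acclimation the trait relaxes on a ~10⁵-year timescale, so
after 2000 years the system sits on a slow acclimation manifold rather
than at a fixed point (end-of-spin-up scaled derivative norms are
~10⁻⁵–10⁻⁴ per month, not < 10⁻⁸; the true interior equilibrium, found
by root-finding, is stationary under the integrator to machine
precision).  `spin_up` therefore warns when the end state is still
drifting, and downstream results should be read as transient dynamics
from a standardised initial protocol, not perturbations of an
equilibrium.  Projection metrics are window means: the decline metric is
`100·(1 − mean(C, 2081–2100)/mean(C, 1986–2005))` over monthly samples
(negative values are increases), and the trait-change metric is the
analogous ratio for *U*.

## Synthetic forcing and observations

Acquiring the hydrographic and CMIP archives behind the original forcing
is out of scope, so experiments run on synthetic monthly SST: a baseline
mean plus a monotone trend (linear by default; affinely rescaled so the
2081–2100 minus 1986–2005 difference hits the scenario's target rise
exactly), a sinusoidal seasonal cycle, and independent Gaussian monthly
noise.  Defaults: seasonal amplitude 1.25 °C and noise 0.35 °C, typical
of tropical reef SST records; scenario rises use the midpoints of the
published ranges (1.0, 1.85, 3.7 °C for low/moderate/high emissions).
Noise is white by design — the variance interpretation stays simple and
the bleaching trigger depends only on monthly exceedances — so the
generator does not reproduce El Niño-like interannual clustering of warm
months, and real records will cluster bleaching events more than the
synthetic ones.  Synthetic cover observations sample the model's own
yearly mean relative abundance at a chosen "true" *N* and add Gaussian
noise (default 2 percentage points) clipped to [0, 100]; they emulate
the noise level, not the survey-design biases, of compiled cover data.
Passing tests on these fixtures demonstrates the estimation machinery
recovers a known truth under realistic noise; it cannot validate the
model against real reefs.

## Calibration

The original selection of *N* was visual; the package formalises it as
least squares between simulated yearly mean relative abundance and the
yearly median of observed percent cover, over a log-spaced candidate
grid (default 12 points per decade on [10⁻¹⁴, 10⁻¹²], the decade
containing all three regional estimates), averaging 10 bleaching
replicates per candidate with replicate seeds shared across candidates.
Candidate simulations are independent of the observations, so the
simulated curves are computed once per grid and reused across noise
realisations in recovery experiments.  Yearly medians of an even count
use the mean of the two middle values.  The calibration era defaults to
the 1970–2010 observation window, and bleaching is on during calibration
(the historical forcing that shaped the observations contained bleaching
years).  Uncertainty is reported only as grid resolution; with
2-percentage-point noise and 40 yearly observations the estimate lands
within one grid step of the truth in ≥ 19/20 repetitions.

## Sensitivity scans

One-at-a-time scans multiply a single parameter by fixed factors
(default 0.75, 1.0, 1.25) and rerun the full protocol over a grid of
speeds of acclimation, recording the time-mean coral abundance over the
whole forced era, replicate-averaged when bleaching is on.  The default
parameter set is the nine physiological constants plus the region's
`K_C`, `σ` and `s`; temperatures are excluded by default because a
percentage of a Celsius reading is not scale-free (they can be perturbed
on request).  "Scaling" is row-wise max-normalisation, chosen to make
the monotonicity of abundance in *N* directly visible per perturbation;
that monotonicity — abundance never decreases with faster acclimation,
whatever the perturbation — holds exactly with bleaching off and within
1 % at 10 replicates with bleaching on.

## Problem sizes

The test-suite and acceptance-script experiments use scaled-down study
designs chosen to exercise every pathway at full fidelity: the spin-up
always runs its full 24,000 months; calibration uses the full 25-point
grid with 10 replicates over a 56-year synthetic record; sensitivity
scans use a 5-point *N* grid over a 96-year record; projections average
a small ensemble (4 forcing realisations × 4 bleaching replicates) of
146-year runs.

## Known limitations

No nutrients, light, acidification, heterotrophy, coral starvation under
heat stress, species resolution, symbiont shuffling, or spatial
structure; degree-heating-week/month stress accumulation metrics are not
used (the event trigger is a simple monthly exceedance).  The model's
absolute abundances inherit the uncertainty of the carrying-capacity
estimates, and — given the slow-manifold caveat above — century-scale
results depend on the standardised spin-up protocol, particularly for
the Great Barrier Reef, whose spin-up state is furthest from
equilibrium.
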