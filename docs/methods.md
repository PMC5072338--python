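# Methods

`circaflux` re-implements, as a tested pipeline, an analysis of circadian
regulation of gas exchange from leaf to canopy scale: a synthetic generator
emulating a controlled-macrocosm (Ecotron-style) experiment, flux
derivation from raw chamber/lysimeter records, penalized-spline trend
analysis with derivative-based significance, quantification of the
clock-driven share of diurnal variation, and AIC-based selection among
stomatal-conductance models with and without a circadian oscillator.

## Experimental protocol emulated

Canopies of bean (*Phaseolus vulgaris*) and cotton (*Gossypium hirsutum*)
are entrained for 5 days under a diurnal cycle patterned on an average
sunny August day in Montpellier — air temperature 28/19 °C max/min, VPD
1.7/0.5 kPa, square-wave PAR of 500 µmol m⁻² s⁻¹ with a 12 h photoperiod
(lights on 06:00) — then PAR, Tair and VPD are held exactly constant for
48 h starting at solar noon. Under constant conditions any persistent
~24 h oscillation must be endogenous. "Subjective day" marks constant-phase
hours that were lit during entrainment.

Within the entrainment days, Tair and VPD follow a 24 h sine peaking at
solar noon and bottoming at midnight. The peak is placed at noon (rather
than mid-afternoon) so that the constant phase, which freezes the drivers
at their solar-noon values, holds them exactly at the stated maxima — the
defining property of the protocol.

## Synthetic data generator

Leaf assimilation is a non-rectangular hyperbola light response
(convexity θ = 0.9) multiplied by a circadian modulation
`1 + amp_a·sin(2πt/24 + phase_a)`. Stomatal conductance follows the Medlyn
unified model `gs = g0 + 1.6(1 + g1/√D)·A/Ca` with the slope oscillating as

    g1(t) = g1m + g1a · sin(g1f·2πt/24 + g1p),   g1f = 1 (24 h period).

Canopy fluxes repeat the leaf-driven signal with every circadian amplitude
multiplied by a `dilution` factor in (0, 1], the expectation being that
shaded, less tightly entrained leaves damp the canopy-scale rhythm; bean
(LAI 7.5) gets a stronger dilution (0.48) than cotton (LAI 4.5; 0.69).
Transpiration converts conductance to a volumetric water flux per
macrocosm (l h⁻¹) via E = gs·(D/P)·M_w·3600·area with P = 101.325 kPa and
a 2 m² ground area; lysimeter mass is the trapezoid-rule integral of E
(1 l ≡ 1 kg) plus optional weighing noise.

Defaults (chosen once; no published ground truth exists): `g1m = 4`,
`g1a = 1` — an amplitude a quarter of the mean slope — with the g1 rhythm
peaking mid-morning (g1p = 1.75π) while the assimilation rhythm peaks at
subjective noon (phase_a = 1.5π; amp_a 0.20 bean / 0.27 cotton). The two
rhythms are deliberately *not* in phase: stomatal and biochemical circadian
outputs are known to be phase-shifted, and exact collinearity of the two
oscillations is a degenerate special case. Noise is additive Gaussian with
AR(1) correlation (ρ = 0.3) at the sampling step; SDs (0.5 µmol m⁻² s⁻¹ on
leaf A, 0.008 mol m⁻² s⁻¹ on gs, 0.4 on canopy A, 0.01 l h⁻¹ on E) give a
conductance-oscillation signal-to-noise ratio above 5 at the default
drivers. Leaf gas exchange is sampled every 4 h in 3 macrocosms per
species; canopy fluxes every 12 min; Ca is fixed at 400 µmol mol⁻¹.
Assimilation is set to zero whenever PAR = 0 (no dark fixation); nocturnal
conductance stays positive through g0 = 0.02 mol m⁻² s⁻¹.

What the generator does *not* emulate: leaf-to-air temperature decoupling
(leaf temperature is set equal to air temperature, a good approximation in
a strongly mixed dome), soil respiration (physically excluded in the
experiment),
hydraulic feedbacks or carbohydrate-accumulation trends (which would be
monotone rather than 24 h-periodic), within-canopy light gradients (the
dilution factor is a lump-sum stand-in), and any relaxation of the rhythm
over prolonged constant conditions. Passing tests therefore demonstrate
that the estimators recover known sinusoidal clock structure at realistic
noise and cadence — not that real canopies behave sinusoidally.

## Trend smoothing and derivative significance

Each flux series is modelled as y_ij(t) = f(t) + b_j + e_ij(t): a cubic
B-spline smooth f penalized by its integrated squared second derivative,
fixed per-macrocosm intercepts b_j (with 3 levels the random-vs-fixed
distinction is immaterial for the shape of f), and AR(1) errors. The
smoothing parameter is selected by GCV on a 49-point log grid spanning
1e−8…1e4 (penalty trace-normalized to the design), with the standard
degrees-of-freedom inflation γ = 1.4 guarding against GCV's tendency to
undersmooth; ties — e.g. when the signal lies in the penalty null space —
resolve to the smoothest candidate. The AR(1) coefficient is estimated
two-stage from pooled lag-1 residual autocorrelation within macrocosm
runs, followed by GLS prewhitening, iterated at most 5 times.

The basis dimension defaults to k = 20 per 72 h window but is capped at
one basis function per two distinct sampling times: with only 19 distinct
4-h leaf sampling times, an unconstrained k = 20 spline oscillates wildly
between spot samples.

First derivatives are computed by central finite differences through the
basis (ε = 1e−3 h, clamped inward at the boundary so edge derivatives are
not halved) on a 500-point uniform grid; pointwise variances come from the
delta method with the Bayesian coefficient covariance σ̂²(XᵀX + λS)⁻¹, and
95 % bounds use the normal 1.96 multiplier. A grid point changes
"significantly" when its derivative interval excludes zero; maximal
significant runs are reported as directed segments. On simulated
constant-mean AR(1) series the pointwise exclusion rate is ~4–5 %
(nominal 5 %).

## Clock-driven variation

For each flux the fitted smooth (never the raw data) is reduced to its
range over the final entrainment day and over the 48 h constant window,
on the fit's evaluation grid (500 points), with fitted values floored at
zero (negative dark-time fluxes lack biological meaning). The clock share
is `100·range_constant/range_entrainment`, reported half-up at 2 decimals.
The zero-floor rule forces the entrainment minimum to 0 — correct for
assimilation (none in darkness) and conservative for conductance and
transpiration (nocturnally above zero), since it enlarges the denominator
and thus under-states the clock share; this monotonicity is asserted as a
property test. A stricter variant restricts constant-phase extrema to
subjective-day grid points, which can only shrink the share.

## Stomatal models and oscillator fitting

Three canonical model families are implemented as pure prediction
functions (with and without minimal conductance g0 — 12 specs in all,
addressable by registry keys `Med`, `Leu+g0`, `Bal+Osc`, …):

- Ball & Berry (1987): gs = g0 + g1·A·h_rel/Ca, with relative humidity
  h_rel = 1 − D/e_sat(T) (Tetens), clipped to [0, 1];
- Leuning (1995): gs = g0 + g1·A/((Ca − Γ)(1 + D/D0)), Γ = 50 µmol mol⁻¹
  and D0 = 1.5 kPa by default (configurable; unreported in the source
  analysis);
- Medlyn et al. (2011): gs = g0 + 1.6(1 + g1/√D)·A/Ca.

Chamber Ca stands in for leaf-surface CO2 throughout (the macrocosms were
strongly mixed). A is always an observed/simulated input, never modelled.

Fitting minimizes the Gaussian negative log-likelihood of observed gs
(equivalently SSE; σ̂² = SSE/n, floored at 1e−24 so exactly-fitting models
compare as equals). Non-oscillator specs are linear and solved exactly.
Oscillator specs inherit g1m from the converged fit of the same family/g0
option without an oscillator and fix g1f = 1; conditional on g1m the
sinusoid is linear in the in-phase/quadrature pair
(a, b) = g1a(cos g1p, sin g1p), so these fits are also exact linear
solves — globally optimal, deterministic, and exactly nested in their
parent (the spec is flagged and excluded from weights if nesting ever
fails numerically). The reflection symmetry (−g1a, g1p) ≡ (g1a, g1p + π)
is resolved to g1a ≥ 0, g1p ∈ [0, 2π). SE(g1a) is reported as the joint
(a, b) uncertainty √(Var a + Var b) — deliberately conservative, because
the delta method collapses at the g1a = 0 null where the phase is free.

The two-step inherited-g1m protocol carries a structural amplitude bias
when a second, correlated oscillation (the assimilation rhythm) is
present: the non-oscillator g1 estimate absorbs part of the oscillation.
Parameter-recovery checks therefore run with the assimilation rhythm
switched off; under its own model the estimator recovers g1a within a few
percent and g1p within ~0.03 rad at the experimental cadence.

AIC = −2L(MLE) + 2p counts structural parameters only (g0, g1 or
g1a + g1p), not σ, uniformly across specs — a constant offset that leaves
AIC differences unchanged. Akaike weights normalize exp(−ΔAIC/2) over the
converged set. Three calibration/validation schemes mirror the experiment:
All→All, Cha→Con (calibrate on the final entrainment day, validate on the
constant window) and Con→Cha. Models are fitted independently per species;
each scheme's AIC row pools the two species (sum of logliks and parameter
counts), and validation R² — the squared Pearson correlation of observed
versus predicted — pools species before computing. Window definitions:
"changing" is the final diurnal entrainment day, "constant" the 48 h
constant-conditions window (reported labelings of these windows are not
always internally consistent; these definitions govern here).

## Flux derivation

Open-chamber net ecosystem exchange is the molar mass balance
`A_c = flow·(c_in − c_out)/area` (µmol m⁻² s⁻¹, positive = uptake;
2 m² ground area by default). Transpiration is the negative smoothed
derivative of lysimeter mass (1.000 kg l⁻¹), using the same penalized
spline; negative rates, possible where the derivative is weakly
constrained near window edges, are floored at zero and flagged. Noiseless
round trips recover a sinusoidal transpiration within 0.2 % away from the
edge 5 % of the window and conserve the integrated mass loss to ~0.2 %.

## Problem sizes and determinism

Monte-Carlo checks use 50 replicates for model selection and parameter
recovery and 200 null series for derivative-CI calibration, sizes at which
the binomial uncertainty on the reported fractions is a few percent. Every
stochastic step flows from a single integer seed (per-species generator
seeds are derived from it), and identical configuration plus seed
reproduces byte-identical CSV output.

## Known limitations

- The smoother's CIs ignore smoothing-parameter and ρ estimation
  uncertainty (as is conventional for penalized-spline intervals).
- The AR(1) estimator assumes regular sampling within macrocosm runs.
- Oscillator amplitude estimates inherit the two-step protocol's bias when
  other correlated rhythms are present (see above); the model-selection
  conclusions are robust to this, the amplitude point estimates are not.
- Ecosystem-scale published percentages are matched only qualitatively:
  recovering them numerically requires the original (undeposited) dataset.
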