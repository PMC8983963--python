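# Methods

This note documents the models implemented in `roastair`, the defaults and
numerical choices, what the synthetic-data generators emulate, and the
limits of what the test suite demonstrates.

## Chamber emission model

A dynamic micro-chamber (reference protocol: 114 mL chamber, 39.4 mL/min
sweep flow, 5.2 g of coffee, exhaust sampled at midpoints 2, 4, 6, 8, 10,
15, 35 and 60 min) measures the concentration of a volatile emitted by a
decaying source. The source's specific emission rate (SER, mg per kg of
coffee per hour) starts at `EF0`, decays exponentially at rate `k` (hr⁻¹),
and approaches a residual steady-state rate `EFss`. With air-exchange rate
`N = Q/V` (hr⁻¹) and loading `L = m/V` (kg/m³), the chamber balance gives

    C(t) = L·EF0·(e^(−kt) − e^(−Nt))/(N − k) + L·EFss·(1 − e^(−Nt))/N .

Both terms are zero at `t = 0`; the second converges to `L·EFss/N`, the
steady concentration a constant source of strength `EFss` would sustain.
The asymptote is carried as a concentration term scaled by `L/N` so that
`EFss` keeps SER units and the model remains a mass balance; an additive
constant in concentration units would be dimensionally inconsistent with
the other parameters and would imply a nonzero concentration at `t = 0`.

**Fitting.** `N` and `L` are measured quantities, fixed from the trial's
geometry and never fitted. The three free parameters are estimated by
trust-region nonlinear least squares from every start on a grid —
`EF0, EFss ∈ {0.1, 1.1, 2.1, 3.1, 4.1}` (0.1–5 by 1) and
`k ∈ {0.1, 1.1, 2.1, 3.1}` (0.1–4 by 1) — with nonnegativity bounds
(`k > 0`). The converged start with the lowest SSE wins (ties broken
toward smaller `k`), and the winner is re-polished at tight tolerances
(ftol = xtol = 1e-15). The grids are treated as multi-start seeds rather
than box constraints: a box would clip legitimate fits (storage trials
reach SERs above 7 mg kg⁻¹ hr⁻¹). An all-zero concentration series is the
exact zero-source fit and short-circuits the optimizer; `k` is then
unidentifiable and reported as a nominal 1 hr⁻¹.

The difference quotient `(e^(−kt) − e^(−Nt))/(N − k)` is evaluated in the
stable form `e^(−kt)·t·φ((N−k)t)` with `φ(x) = (1−e^(−x))/x`, so the fit
can approach the removable `k = N` singularity without cancellation;
exact coincidence is rejected with an error, and grid starts that land on
`N` are nudged by 1e-6 relative.

**Derived emission factors.** The curve's maximum on `(0, t_end]`
(`t_end` = last midpoint) is located by a 1e-4-hr grid scan polished with
bounded scalar minimization (xatol 1e-12); with `EFss = 0` it matches the
closed form `t_max = ln(N/k)/(N−k)` to better than 1e-6 hr. A curve still
rising at `t_end` (pure asymptote, `EF0 = 0`) is flagged as a boundary
maximum. Then

    EFmax = Cmax·N/L = Cmax·Q/m ,
    EFbuildup = EFmax / (1 − e^(−N·t_max)) .

`EFbuildup` is a transient mass-balance correction: by the peak time the
chamber has only equilibrated to the fraction `1 − e^(−N·t_max)` of a
constant source's steady response, so the source strength consistent with
the observed peak is `EFmax` *divided* by that fraction, which makes
`EFbuildup ≥ EFmax` always, approaching equality as `N·t_max → ∞`. A
multiplicative form would fall below `EFmax`, contradicting both the
physics and the intended meaning of a buildup adjustment.

## Summaries

SER replicates are summarized arithmetically (mean, SD with the n−1
denominator — the conventional choice for n = 3 replicate groups —
CV = 100·SD/mean, extremes). Storage-age trends use ordinary least
squares of SER on day with a 95% CI on the slope from the t distribution
(n−2 df). Particle Feret diameters are lognormal, so they are summarized
geometrically: `GM = exp(mean ln d)`, `GSD = exp(SD ln d)` (n−1).

The Feret (caliper) diameter of a 2-D outline along a direction is the
width of the projection onto that direction. The maximum over directions
equals the largest pairwise distance between convex-hull vertices and is
computed exactly that way (Qhull, with an all-pairs fallback for
degenerate/collinear outlines); directional values are available on any
requested angle for per-angle reporting.

## Two-zone dispersion model

A hemispherical near field (radius 0.75 m by default, volume
`⅔πr³ ≈ 0.884 m³`, free-slip boundary `A_FS = 2πr² ≈ 3.53 m²`) surrounds
worker and source inside a room ventilated with clean supply air `Q`.
The inter-zone flow is `β = ½·s·A_FS` with `s` the random air speed at the
boundary; the default radius was chosen so that the standard air-speed
range 1–24 m/min maps onto β ≈ 1.77–42.4 m³/min. The coupled balances
(see README) assume instantaneous mixing within each zone, clean supply
and initial air, and exhaust as the only sink.

The system is linear and is solved exactly: eigendecomposition of the
2×2 rate matrix (both eigenvalues real and negative; the matrix is
similar to a symmetric one via diagonal scaling), with
`x(t) = x_ss + Σ cᵢ e^(λᵢt) vᵢ`. A repeated eigenvalue (measure-zero in
parameters) falls back to the confluent form `e^(λt)(a + bt)`. The same
decomposition yields closed-form running integrals `∫₀ᵗ C dτ`, used for
exact TWAs and for the mass-conservation check
`Q·∫C_F + V_N·C_N(T) + V_F·C_F(T) = G·T`. A fixed-step RK4 integrator
lives in the test suite as an independent oracle, not in the package.

Concentration-to-mixing-ratio conversion uses the molar volume 24.45
L/mol (25 °C, 1 atm): `ppb = C[mg/m³]·1000·24.45/M` with molar masses
86.09 (diacetyl) and 100.12 g/mol (2,3-pentanedione).

## Scenario engine

A shift is an ordered sequence of segments; the worker is near-field
(packaging, grinding — must resolve to a generation rate
`G = SER·mass/60`), far-field (gaps, cleaning/labeling), or off exposure
(breaks, lunch — concentration 0 by definition). The room's two-zone
state evolves continuously across the whole shift with sources active
only during their own segments. At the start of each near-field task both
zones are initialized at the prevailing far-field concentration — the
worker walks up to an already-ventilated room, and the small near-field
zone re-forms around the new source. Far-field exposure between tasks is
the *evolving* far-field state, not a fixed background.

The presets describe a small facility (scenario A: 10 kg dark roast per
task, 15-min grinding, room 7787 m³, Q = 73.2 m³/min) and a medium one
(scenario B: 181.8 kg per task, 1-min grinding, room 31856 m³,
Q = 265.45 m³/min). Each cycle is three 15-min packaging tasks and one
grinding task, each followed by a 5-min far-field gap, then a 15-min
cleaning/labeling block; four cycles with two 15-min breaks and a 30-min
lunch interleaved at roughly quarter points, padded to exactly 480 min
with a far-field wrap-up block (40 min in A, 96 min in B). Full-shift
TWAs are insensitive to the ordering; only the shape of the running-TWA
curve depends on it. Central generation rates ship with the presets as
the published scenario inputs (A: 0.035 and 0.6 mg/min; B: 0.64 and
10.9 mg/min — the dark-roast whole-bean/fine-ground SERs 0.21 and
3.60 mg kg⁻¹ hr⁻¹ applied to the per-task mass and quoted at input
precision); the SER and mass remain on the segments as provenance.

Per-segment and running TWAs use the exact analytic integrals, so the
running TWA at shift end equals the full-shift TWA identically. The
exceedance report compares the full-shift TWA to a REL (default 5.0 ppb,
diacetyl) and short-term exposure to a STEL (default 25 ppb) two ways:
the maximum rolling 15-min TWA (1-min step, from the exact cumulative
integral) and the maximum per-task TWA ratio. Limits are configuration
constants, never hard-coded. A post-hoc sanity bound checks each task's
emitted mass `G·duration` against the total chemical content of the
coffee handled (default 19 µg diacetyl per g coffee): a model emitting
more than a few percent of the available mass would be unphysical; both
presets stay below 5%.

## Monte Carlo

Input distributions follow the conventions of probabilistic exposure
modelling: measured flows → uniform over the stated range; generation
rates → normal with the stated ±95% CI half-width converted to
sd = half-width/1.96 (e.g. 0.6 ± 0.14 mg/min → sd 0.0714); known
constants → fixed. Normal draws of physically positive quantities are
truncated at zero by rejection sampling, with rejected-draw counts
reported (the whole-bean generation rate 0.035 ± 0.24 mg/min would
otherwise be negative in ~39% of draws — the reported truncation count
makes this visible rather than silent). Default iteration count is
10,000 with a mandatory explicit seed; percentiles use linear
interpolation between order statistics. The Monte Carlo standard error of
the median is estimated by batching (10 contiguous batches). Draw
failures are skipped and counted; a failure fraction above 1% aborts the
run. Distribution keys name what they perturb (`supply_air`,
`interzone_flow`, `generation:<label>`), so the same machinery drives any
schedule.

The β distribution used for the published percentile outputs is not
derivable from the scenario descriptions, so the presets default to a
fixed β from the near-field geometry; the sensitivity sweep covers the
documented 1.77–42.4 m³/min span instead. Reported per-task medians are
therefore comparable in magnitude but not numerically identical to the
published percentile outputs, and those outputs are deliberately not
asserted by the tests.

**Sensitivity to β.** At steady state `C_N = G/Q + G·(1/β)` — exactly
linear in 1/β with slope `G` and intercept `G/Q` (in ppb units after
conversion). The sweep evaluates the near-field steady state across a β
grid, fits the line (residuals are zero to round-off), and reports
fold-changes between grid points; in still air (β 1.77 → 5.3 m³/min) the
concentration drops ~2.9-fold at the small-facility central inputs.

## Synthetic data

The generators define the study conditions under which the pipeline is
tested:

* **Chamber series**: model curve at the reference design's eight
  midpoints times independent unit-median lognormal noise
  (`σ² = ln(1+CV²)`). Multiplicative noise was chosen because chamber
  concentrations are positive and measurement error scales with level;
  no instrument noise model is published for this protocol, and the
  default CV of 0.05 in examples/tests is a package choice. Sample
  durations (30 s for the first five samples, 1 min for the last three)
  are carried as metadata; concentrations are generated at the midpoint
  instant, matching how the measured curves are analyzed.
* **Particle samples**: lognormal draws parameterized by GM/GSD; fixture
  values (e.g. GM 0.036 cm, GSD 2.0 for coarse grounds) match the
  magnitudes of the measured forms.
* **Storage series**: linear trend plus Gaussian noise, for testing the
  trend estimator.

Ground-truth parameter sets in fixtures use SER magnitudes of 0.1–4
mg kg⁻¹ hr⁻¹, the range spanned by the measured fresh-roast SERs. What
passing tests show: the estimators recover the parameters of data
generated by their own model (round-trip identity, noiseless ≤ 0.1%;
noisy median EF0 within 5% over 100 seeds). What they do not show:
robustness to model misspecification (non-first-order decay, drifting
chamber flow, correlated instrument error), which real chamber data may
exhibit.

## Numerical choices and degenerate inputs

* Fit tolerances: per-start ftol/xtol/gtol 1e-10 (max 200 evaluations),
  final polish 1e-15; peak scan 1e-4 hr then bounded polish.
* `k = N` rejected; near-degeneracy handled by the stable `φ` form.
* Eigenvalue coincidence in the two-zone solver (relative gap < 1e-9)
  switches to the confluent analytic form.
* Schedules must sum to the shift length to 1e-9 min; the residual is
  reported on failure.
* Scenario simulation grid: 0.05 min for deterministic profiles, 0.1–0.25
  min inside Monte Carlo loops (TWAs are exact regardless of grid; the
  grid only shapes the sampled curves and the rolling-STEL scan).
* Problem sizes: the randomized analytic-vs-RK4 sweep uses 100 parameter
  draws at 1-ms steps over 2 h; the noisy-recovery study uses 100 seeds;
  script-level Monte Carlo summaries use 400 draws (batch SE ~2% of the
  median), all chosen to run on a laptop in about a minute.

## Known limitations

* The constant-generation model ignores source decay within a task;
  fine for ≤15-min tasks given the fitted decay constants, but long
  storage-bin scenarios would need the decaying-source generation form.
* Near-field geometry is a modelling choice (hemisphere, r = 0.75 m)
  exposed as configuration; real facilities differ.
* No surface sorption, chemical reaction sinks, cross-drafts, or
  worker-to-worker variability.
* SER inputs are specific to the tested coffee, roast levels, grind
  sizes, and laboratory temperature/humidity; predictions should be
  confirmed with air sampling before use in compliance decisions.
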