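# roastair

Emission-chamber kinetics and two-zone occupational exposure modelling for
the alpha-dicarbonyl volatiles emitted by roasted coffee — diacetyl
(2,3-butanedione) and 2,3-pentanedione. Both compounds are respiratory
hazards (diacetyl inhalation is associated with obliterative bronchiolitis),
and workers in coffee roasting and packaging facilities can be exposed above
occupational limits when handling ground coffee near the source.

The package is aimed at industrial hygienists and exposure modellers. It
covers the full chain from raw chamber measurements to probabilistic
full-shift exposure estimates:

1. **Chamber kinetics** (`roastair.chamber`). A mass *m* of coffee in a
   micro-chamber of volume *V* swept at flow *Q* produces an exhaust
   concentration that follows the first-order decaying-source model

   ```
   C(t) = L·EF0·(e^(−kt) − e^(−Nt))/(N − k) + L·EFss·(1 − e^(−Nt))/N
   ```

   with loading factor `L = m/V` (kg/m³) and air-exchange rate `N = Q/V`
   (hr⁻¹). Nonlinear least squares (multi-start over a grid of initial
   values, nonnegativity constraints) estimates the initial specific
   emission rate `EF0`, the steady-state asymptote `EFss`, and the decay
   constant `k`. The fitted curve's peak gives
   `EFmax = Cmax·N/L = Cmax·Q/m`, and the transient mass-balance
   correction `EFbuildup = EFmax/(1 − e^(−N·tmax)) ≥ EFmax` accounts for
   the chamber's incomplete response at the peak time.

2. **Summaries** (`roastair.summary`). Replicate SER statistics
   (mean, SD, CV), least-squares storage-age trends with 95% confidence
   intervals, lognormal particle-size summaries (GM/GSD), and Feret
   (caliper) diameters of 2-D outlines, including the exact maximum-caliper
   width via the convex hull.

3. **Two-zone model** (`roastair.twozone`). A near-field zone (hemisphere
   around worker and source, inter-zone flow `β = ½·s·A_FS`) coupled to the
   far field of a ventilated room:

   ```
   V_N·dC_N/dt = G + β·(C_F − C_N)
   V_F·dC_F/dt = β·(C_N − C_F) − Q·C_F
   ```

   solved exactly through its two eigenvalues, with closed-form running
   time integrals (so TWAs are quadrature-free). Steady state:
   `C_F = G/Q`, `C_N = G/Q + G/β`.

4. **Scenario engine** (`roastair.scenario`). Cyclic 8-h work schedules
   (built-in small- and medium-facility presets), continuous far-field
   evolution across the shift, per-task and full-shift TWAs, emitted-mass
   accounting, and REL/STEL exceedance reports.

5. **Monte Carlo** (`roastair.montecarlo`). Uniform/normal/fixed input
   distributions with positive truncation, seeded propagation through the
   scenario engine, median/95th-percentile summaries, and the inter-zone
   flow sensitivity sweep (near-field concentration is exactly linear in
   1/β).

6. **Synthetic data** (`roastair.synthetic_data`). Seeded generators with
   known ground truth for chamber series, particle samples, and storage
   series, so the whole pipeline is testable without laboratory data.

## Worked example

```python
import numpy as np
import roastair as ra

# Fit a chamber trial (here synthetic, with known truth and no noise).
design = ra.reference_design()          # 114 mL, 39.4 mL/min, 5.2 g, 8 midpoints
truth = ra.TrueEmissionParams(ef0=2.0, ef_ss=0.5, k=1.0, seed=7, noise_cv=0.0)
fit = ra.fit_emission_curve(ra.gen_chamber_series(design, truth))
print(fit.ef0, fit.ef_ss, fit.k)        # 2.0000 0.5000 1.0000  (exact recovery)
print(fit.c_max, fit.ef_max, fit.ef_buildup)

# Simulate a shift in the small-facility preset and inspect exposures.
profile = ra.simulate_schedule(ra.scenario_a(), ra.default_system("scenario_A"))
print(ra.full_shift_twa(profile))
print(np.mean(profile.per_task_twa["grinding"]))
print(profile.emitted_mass_by_task["grinding"][0])
```

prints (trailing digits abbreviated):

```
EF0=2.0000  EFss=0.5000  k=1.0000
Cmax=4.832 mg/m3   EFmax=2.197   EFbuildup=2.272 mg kg-1 hr-1
full-shift TWA      = 2.58 ppb
grinding task TWA   = 16.3 ppb
emitted per grind   = 9.0 mg
```

Reading: the synthetic trial's source parameters are recovered exactly;
in the small-facility scenario (10 kg dark-roast per task, β = 10.6
m³/min) a grinding task averages ~16 ppb of diacetyl in the near field,
each grinding task releases 9 mg of diacetyl, and diluting over the whole
480-min shift the worker's TWA is ~2.6 ppb — between the 5-ppb full-shift
REL and typical far-field levels, exactly the regime where task pattern
and proximity to the source decide compliance.

The same functionality is scriptable from the shell:

```
roastair gen --out trials.csv --seed 1
roastair fit --trials trials.csv --out fits.json
roastair simulate --scenario scenario_A --out profile.csv
roastair sensitivity --beta-grid 1.77,5.3,10.6,42.4 --out sweep.csv
```

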