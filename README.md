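# coralacclim

A trait-based simulator of coral–algae symbiosis under ocean warming, for
theoretical ecologists and reef modellers who want to explore how fast
coral communities must acclimate to keep pace with rising sea-surface
temperatures.

## The model

Reef-building corals host photosynthetic algae (zooxanthellae) whose
carbon subsidises coral growth; heat stress breaks the symbiosis down
(bleaching).  The simulator couples three state variables — coral
abundance *C* (cm²), symbiont abundance *S* (cells) and a community-mean
energy-investment trait *U* — through

```
dC/dt = F(U, S, C) · C
dS/dt = G_S(T) · (1 − S/K_S(C)) · S
dU/dt = N · ∂F/∂U
```

with coral fitness

```
F = G_C(T) · κ(S) · E(U) · (1 − C/K_C) − μ(U, S) − M_C
κE  = S/(Γ_h·C + S) · (1 − e^(−β·U))        (symbiotic feedback)
μ   = α · e^(r·U) · S/K_S                    (symbiotic cost)
```

`G_C(T)` is a skew-normal thermal performance curve normalised to its
mode, `G_S(T) = a·e^(b·T)` is the symbiont thermal growth envelope, and
`K_S = K_smax·C` ties the symbiont carrying capacity to the living coral
area.  The trait *U* is the energy a unit of coral surface invests in the
symbiosis each month; it climbs the fitness gradient at the **speed of
acclimation** *N* — the model's key parameter, estimated by fitting
simulated relative coral cover to yearly medians of observed percent
cover.  Bleaching is a stochastic event process: whenever monthly SST
exceeds the regional optimum `T_opt` by a margin inside an observed
exceedance band, *S* is cut by a percentage drawn uniformly from that
band's observed reduction range.

Three region presets ship with the package (Great Barrier Reef, South
East Asia, Caribbean), each with its published thermal curve, carrying
capacity, bleaching bands, fixed spin-up temperature and speed of
acclimation.  The experiment protocol is: a 2000-year spin-up at the
fixed regional temperature, then a monthly-forced run (historical record
plus a warming scenario) with bleaching checks each month.

## Worked example

Fit the speed of acclimation to noisy synthetic cover observations and
project a high-emissions scenario:

```python
from coralacclim import (
    CoralAcclimationModel, GlobalParams, RunSettings, ScenarioSpec,
    decline_metric, region_preset, synthetic_cover, synthetic_forcing,
)

gbr = region_preset("GBR")
forcing = synthetic_forcing(ScenarioSpec(
    baseline_mean=gbr.spinup_T, target_rise=0.6, seed=101, span=(1955, 2010)))
obs = synthetic_cover(gbr, GlobalParams(), forcing, N_true=5.54e-13,
                      noise_sd=2.0, years=range(1971, 2011), seed=7,
                      settings=RunSettings(seed=999))

model = CoralAcclimationModel(obs, forcing, region="GBR")
res = model.fit(replicates=10)
print(res.summary())

scenario = synthetic_forcing(ScenarioSpec(
    baseline_mean=gbr.spinup_T, target_rise=3.7, seed=11))
traj = res.simulate(scenario)
print(f"bleaching events 1955-2100:   {len(traj.events)}")
print(f"projected decline 2081-2100:  {decline_metric(traj):.1f} %")
```

which prints

```
Coral acclimation model - speed of acclimation fit
====================================================
Region:                 GBR
Observation years:      1971-2010 (40 yearly medians)
Candidate grid:         25 points, [1e-14, 1e-12]
Bleaching replicates:   10
N (speed of acclim.):   5.623e-13 (energy cm^-2 month^-1)^2
Grid neighbours:        [4.642e-13, 6.813e-13]
RMSE (yearly cover):    5.597 percentage points
====================================================
bleaching events 1955-2100:   848
projected decline 2081-2100:  42.8 %
```

The fitted `N = 5.62e-13` recovers the generating value `5.54e-13`
within one step of the 12-points-per-decade grid; the RMSE reflects the
2-percentage-point observation noise plus bleaching stochasticity.  Under
a scenario warming 3.7 °C by 2081–2100 (the midpoint of the
high-emissions range) the mean coral abundance of that window falls
42.8 % below the 1986–2005 baseline.

The same experiments are available from the shell:

```
coralacclim synth-forcing --rise 3.7 --baseline 25.90 --seed 11 --out rcp85.csv
coralacclim run --region GBR --forcing rcp85.csv --seed 1 --out run_out
coralacclim run --region GBR --forcing rcp85.csv --no-bleaching --no-acclimation --out ablation
coralacclim calibrate --region GBR --forcing hist.csv --obs cover.csv --out cal_out
coralacclim sensitivity --region GBR --forcing rcp85.csv --out sens_out
```

Every command writes a `manifest.json` (config hash, seed, versions,
runtime) sufficient to re-run bit-identically.

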