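# cassleaf

Steady-state and dynamic analysis of cassava leaf photosynthesis, plus a
reduced coupled leaf simulator for fluctuating-light experiments.

The package covers the full computational chain used to diagnose what limits
leaf carbon uptake in cassava:

* **`cassleaf.fvcb`** — the biochemical demand model of C3 photosynthesis
  (carboxylation / RuBP-regeneration / triose-phosphate-limited rates),
  temperature responses, the non-rectangular light response of electron
  transport, and closed-form coupling of demand to the stomatal + mesophyll
  CO2 diffusion path.
* **`cassleaf.steady_state`** — CO2-response (A/Ci) curve fitting with
  breakpoint search and optional TPU ceiling, joint compensation-point /
  respiration / mesophyll-conductance estimation from paired chlorophyll
  fluorescence (variable-J family), chloroplast-basis capacity refits,
  Grassi–Magnani-style limitation partitioning, and intrinsic water-use
  efficiency.
* **`cassleaf.dynamics`** — shade-to-sun induction metrics (T50A, T90A,
  cumulative fixation, T50gs, gsT0), exponential fitting of stomatal
  conductance transients (k_i / k_d), time-resolved Vcmax and stomatal
  limitation from multi-CO2 induction sets, and Ball–Berry slope/intercept
  fitting from light curves.
* **`cassleaf.simulator`** — a two-state dynamic leaf model (stomatal
  conductance relaxing toward a Ball–Berry target; Rubisco activation
  relaxing toward a light-dependent level, slowed at low intercellular CO2)
  driving the demand model, with scenario experiments: kinetics multipliers
  and carbon/water-use-efficiency losses over repeated low/high light cycles.
* **`cassleaf.synth`** — synthetic gas-exchange data (A/Ci curves, induction,
  relaxation and light-response traces) generated from known parameters with
  Gaussian instrument noise, so every analysis stage is testable without
  instrument files.
* **`cassleaf.gasex` / `cassleaf.tables`** — CSV trace I/O (native and a
  LI-6400-style tabular dialect), mean ± SE summaries, and the bundled
  13-cultivar trait tables used for presets and acceptance checks.

## Command line

All functionality is exposed through one entry point:

```bash
# generate synthetic data
cassleaf synth aci --preset fast --seed 1 -o aci.csv
cassleaf synth induction --preset slow --no-noise -o induction.csv
cassleaf synth relaxation --preset fast -o relax.csv

# steady-state analysis
cassleaf fit-aci aci.csv
cassleaf fit-gm aci.csv
cassleaf limitations aci.csv

# dynamics
cassleaf induction induction.csv
cassleaf kinetics relax.csv --start-s 4800
cassleaf ball-berry lightcurve.csv

# simulation
cassleaf simulate --preset slow --dt 0.5 -o sim.csv
cassleaf scenarios --preset slow --ki-mult 3
cassleaf diurnal-loss
```

Presets are the 13 cultivar names from the bundled trait tables plus the
aliases `fast` and `slow` (largest / smallest dark-adapted conductance).

## Notes on model scope

The simulator intentionally reduces the leaf to two kinetic state variables
on top of the steady-state demand model; explicit Calvin-cycle metabolite
pools are out of scope.  Two conductance-coupling modes are provided:
`assimilation` (the target follows the instantaneous assimilation rate;
default) and `steady` (the conductance relaxes exponentially toward the
current light phase's coupled steady state, making the fitted transient
time constants exact).  See the `cassleaf.simulator` docstrings for when
each is appropriate.
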