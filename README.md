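# memphys

Analysis toolkit for measuring how small amphiphilic solutes — serotonin in
particular — alter the physical properties of model lipid membranes. It
implements the four measurement chains of a droplet-interface-bilayer (DIB)
study, each as a tested, reusable module:

* **Osmotic water permeability (Pf).** Two monolayer-coated droplets joined
  by a bilayer exchange water under an osmotic gradient. The volume flux
  follows `dV/dt = Pf · Vw · A · Δc`, with `Vw` the molar volume of water,
  `A` the bilayer area and `Δc` the osmolar concentration difference.
  `simulate_osmosis` integrates this law; `OsmoticPermeabilityModel.fit()`
  estimates Pf (μm/s) from a droplet-diameter time series by an initial-rate
  or full ODE fit.
* **Bilayer tensiometry.** The mechanical balance at the contact line gives
  `γ_b = 2 γ_m cos θ`; the module turns monolayer tensions and contact
  angles into bilayer tensions and control-normalized dose-response tables.
* **DSC thermogram reduction.** Baseline subtraction followed by the main
  transition temperature `Tm` (peak position), calorimetric enthalpy `ΔH`
  (integral of the excess heat capacity) and peak width (fwhm).
* **Raman C–H order ratios.** Band intensities at ~2850/2890/2930 cm⁻¹ and
  the disorder ratios I2930/I2890 and I2930/I2850, after polynomial
  baseline correction, 2850-normalization and scaled subtraction of the
  serotonin spectrum (anchored on its 1540 cm⁻¹ indole band).

A statistics layer (two-way fixed-effects ANOVA with interaction, Tukey HSD
via an in-package studentized-range CDF) and seeded synthetic-data
generators for every input complete the pipeline. Droplet-pair geometry,
including circle detection in grayscale droplet images, lives in
`memphys.geometry`.

## Worked example

```python
import numpy as np
from memphys import bilayer_tension, estimate_pf, simulate_osmosis, OsmoticState
from memphys.geometry import geometry_from_diameters_and_theta

# bilayer tension of a DOPC DIB without serotonin: gamma_m = 1.125 mN/m,
# contact angle 31.20 deg
print(round(bilayer_tension(1.125, 31.20), 2))   # -> 1.92  (mN/m)
# ... and at 40 mM serotonin for DOPC/SM/Chol (1:1:0.2)
print(round(bilayer_tension(0.428, 35.95), 2))   # -> 0.69

# recover Pf from a simulated control trace: two 100 um droplets,
# 186 mOsm/kg gradient, 31.2 deg contact angle
geom = geometry_from_diameters_and_theta(100, 100, 31.2)
state = OsmoticState.from_diameters(100, 100, geom.Ab, 186.0)
trace = simulate_osmosis(state, Pf=73.0, t_grid=np.arange(0, 61.0))
print(estimate_pf(trace, geom).summary())
```

```
1.92
0.69
Osmotic water permeability fit
==============================
method:          ode_fit
n frames:        61
Pf:              73.000 um/s
Pf std err:      0.000 um/s
rms residual:    9.030e-16 (relative)
```

The serotonin-free DOPC bilayer has a tension of 1.92 mN/m, dropping to
0.69 mN/m for the ternary raft mixture at 40 mM serotonin — adsorption of
the amphiphilic cation loosens the interface. The permeability fit recovers
the generating Pf of 73 μm/s exactly on a noiseless trace; on real traces
the relative rms residual diagnoses measurement noise.

From a shell, the same chains are available as subcommands
(`memphys simulate-dib | estimate-pf | tension | dsc | raman | anova |
synth | run-all`); `memphys run-all --synthetic --seed 7` writes a full
report bundle for a synthetic 3-membrane × 6-concentration study.

## Layout

```
src/memphys/     geometry, osmosis, tensiometry, calorimetry, raman,
                 stats, synthetic, pipeline, io, cli, datasets
tests/           pytest suite (unit, property and acceptance tests)
docs/methods.md  models, conventions, parameter choices, limitations
```
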