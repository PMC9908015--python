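# aptaruler

Simulation and analysis toolkit for a tethered-nanoparticle plasmonic
aptasensor for bacterial endotoxin (lipopolysaccharide, LPS).

## The sensing principle

An 80-nm gold nanoparticle (AuNP) is tethered to a gold nanofilm (AuNF)
by a single 66-nt ssDNA aptamer. The aptamer's central 36-nt region
folds around an endotoxin molecule on binding, shortening the effective
tether and pulling the particle closer to the film. Because the
particle–film plasmon coupling is strongly distance dependent, binding
red-shifts the dark-field scattering spectrum. The readout is the **RG
ratio** — scattered intensity at a red wavelength over a green one,
RG = SC_R/SC_G — which is immune to multiplicative offsets in
excitation or collection efficiency. The sensor works in two modes:
*ensemble* (microspectrometer averaging many particles) and
*single-particle* (per-spot color-camera RG with single-molecule
resolution).

`aptaruler` implements the full computational machinery around this
sensor:

- **`tether`** — the aptamer + linkers as a composite worm-like chain;
  Monte Carlo sampling of the particle–film gap z under half-space
  boundary conditions, for the unbound tether and for the bound state
  with a rigid 2–4 nm aptamer–endotoxin complex.
- **`energy`** — inverse Boltzmann statistics, E(z) = −kT ln p(z), and
  the force field −dE/dz.
- **`dynamics`** — overdamped (Euler–Maruyama) Brownian dynamics of the
  gap coordinate in that potential of mean force, with Stokes–Einstein
  diffusion and reflecting walls.
- **`scattering`** — a calibrated two-Lorentzian plasmon-ruler
  surrogate mapping gap → spectrum (green mode ~600 nm, coupled red
  mode ~720 nm whose amplitude decays exponentially with the gap), plus
  time-averaged spectra and RG extraction.
- **`ensemble`** — experimental ensemble-mode pipeline: background/
  excitation correction, ln-linear calibration RG = a·ln C + b, limit of
  detection bracketing, EU↔ng conversion, Student's t / one-way ANOVA.
- **`singleparticle`** — spot detection in RGB dark-field frames,
  per-particle aperture-photometry RG, population-shift statistics, and
  nearest-neighbour spacing.
- **`qcm`** — Sauerbrey conversion of quartz-crystal-microbalance
  frequency drops to areal mass, oligo molecular weight, surface
  density, coupling/bound fractions, and binding-slope fits.
- **`synthetic`** — generators for every input (spectra, dark-field
  frames, titrations, QCM traces) with ground-truth sidecars, so the
  whole pipeline is testable without any experimental data.

## Worked example

```python
import numpy as np
from aptaruler import (
    build_tether_spec, sample_chain_conformations, summarize_z,
    invert_boltzmann, simulate_trajectory, time_averaged_spectrum, rg_ratio,
    synth_titration, fit_calibration, estimate_concentration,
)

# 1. tether Monte Carlo: unbound vs endotoxin-bound
unbound = build_tether_spec(state="unbound")
bound = build_tether_spec(state="bound", endotoxin_length=3.0)
z_u = sample_chain_conformations(unbound, n_chains=100_000, seed=1)
z_b = sample_chain_conformations(bound, n_chains=100_000, seed=1)
su, sb = summarize_z(z_u), summarize_z(z_b)
print(f"mean gap unbound: {su.mean:.2f} +/- {su.sd:.2f} nm")
print(f"mean gap bound:   {sb.mean:.2f} +/- {sb.sd:.2f} nm")

# 2. Brownian dynamics in the inverted energy landscape
profile = invert_boltzmann(su.bin_centers, su.density)
traj = simulate_trajectory(profile, dt=1e-8, n_steps=1_000_000, seed=2)
print(f"diffusion coefficient: {traj.diffusion_coefficient:.2e} m^2/s")

# 3. time-averaged plasmon spectra and the RG ratio (simulation: 720/600 nm)
rg_u = rg_ratio(time_averaged_spectrum(traj.z), red_wl=720, green_wl=600)
rg_b = rg_ratio(time_averaged_spectrum(z_b.z_values), red_wl=720, green_wl=600)
print(f"RG unbound: {rg_u:.3f}   RG bound: {rg_b:.3f}")

# 4. ensemble calibration on a synthetic titration
df, _ = synth_titration(seed=3)
levels = sorted(df["concentration_eu_ml"].unique())
fit = fit_calibration(levels, [df.loc[df.concentration_eu_ml == c, "rg"] for c in levels])
print(f"RG = {fit.slope:.3f} ln(C) + {fit.intercept:.3f}  (R^2 = {fit.r_squared:.3f})")
print(f"RG 1.40 -> {estimate_concentration(fit, 1.40):.0f} EU/ml")
```

Output:

```
mean gap unbound: 7.21 +/- 4.09 nm
mean gap bound:   5.25 +/- 3.02 nm
diffusion coefficient: 6.13e-12 m^2/s
RG unbound: 1.214   RG bound: 1.580
RG = 0.107 ln(C) + 0.896  (R^2 = 0.994)
RG 1.40 -> 113 EU/ml
```

The unbound tether holds the particle ~7.2 nm above the film; binding a
3-nm endotoxin complex pulls it down to ~5.3 nm, raising the simulated
RG from ~1.21 to ~1.58. The synthetic titration (generated with slope
0.106, intercept 0.902, replicate sd 0.015) is recovered by the
ln-linear fit, and the inverted calibration turns an RG reading back
into a concentration.

A `aptaruler` command-line tool wraps the same functionality
(`simulate-tether`, `energy`, `simulate-bd`, `spectrum`, `rg`,
`calibrate`, `lod`, `sp-analyze`, `qcm`, `synth ...`); run
`aptaruler --help`.

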