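# Methods

## Tether model

The film-to-particle tether is a composite worm-like chain sampled at
Kuhn-segment resolution as a freely jointed chain: each flexible ssDNA
stretch is split into links of one Kuhn length (plus one remainder link
so the contour is exact), each rigid element (surface linkers, the
folded aptamer–endotoxin complex) is a single rod, and every link takes
an independent orientation uniform on the sphere. Only the z-components
of the walk are generated: the in-plane components decouple from every
constraint and observable used here.

Geometry defaults:

| parameter | value | why |
|---|---|---|
| ssDNA rise | 0.63 nm/nt | standard ssDNA contour rise |
| ssDNA Kuhn length | 2.6 nm | persistence ~1.3 nm, within the ssDNA literature range at moderate ionic strength; see calibration note below |
| rigid end linker | 2.5 nm each end | extended HSC11EG6 SAM arm + amide + amino-C6 on the film side; thiol anchor on the particle side |
| binding region | central 36 nt of the 66-nt construct | folds into a rigid 2–4 nm complex in the bound state, leaving two 15-nt flexible arms |
| particle | 80 nm Au sphere | enters the Brownian dynamics through Stokes–Einstein |

The ssDNA Kuhn length and linker length are a one-time calibration:
with rise fixed at 0.63 nm/nt they were chosen, within their literature
ranges, so the unbound and bound ensemble means land on the
experimental tether heights (~7.1 and ~5.4 nm). They are package
defaults, not fitted per run.

z convention: z is the gap between the film surface (z = 0) and the
tether's particle-side end, i.e. the chain end-to-end z-extension. The
particle is attached at its lowest pole and particle rotation is
ignored, so sphere–film non-penetration coincides with z ≥ 0.
Conformations with any chain node below the film are rejected and
resampled, so an ensemble always holds exactly `n_chains` gaps.
Chain–particle excluded volume is neglected (standard tethered-particle
simplification; the film constraints dominate).

## Energy landscape

Inverse Boltzmann statistics: E(z) = −ln p(z) in kT, shifted to
min 0, on a uniform grid (default bin width 0.25 nm — ≥ 30 bins across
the ~7-nm scale without starving counts at 10⁵ chains). Bins never
visited get a finite cap, max observed energy + 5 kT, keeping the force
field finite; equilibrium dynamics essentially never reaches them. The
force is the negative centered finite difference (one-sided at the
ends), linearly interpolated between bin centers on query.

## Brownian dynamics

Euler–Maruyama integration of the overdamped Langevin equation with
D = kT/(6πηR) (water at 298 K, 8.9×10⁻⁴ Pa·s by default; D ≈
6.1×10⁻¹² m²/s for the 80-nm sphere), default Δt = 10⁻⁸ s giving a
~0.35-nm thermal step. The integrator aborts if the thermal step
exceeds five profile bins. Reflecting walls sit at z = 0 *and* at the
top edge of the profile support: the tether cannot extend beyond the
range the Monte Carlo ensemble reaches, and without upper confinement a
flat profile would let the particle leave the support. D is constant in
z; near-wall hydrodynamic hindrance rescales time but not the
equilibrium distribution, and only equilibrium statistics feed the
optical signal. The initial position is drawn from the profile's own
equilibrium density, removing burn-in sensitivity. Default run length
10⁶ steps (10 ms simulated) keeps a desk-scale run in seconds while
giving ~10⁴–10⁵ correlation times in the tether potential.

## Scattering surrogate

Full electromagnetic (boundary-element) scattering is out of scope; the
gap → spectrum map is a two-Lorentzian plasmon-ruler surrogate:

- green mode: center 600 nm, FWHM 90 nm, amplitude 1 − 0.5·e^(−z/d);
- red (coupled) mode: amplitude 4·e^(−z/d), center relaxing 720 → 680
  nm as e^(−z/d), FWHM 90 nm; coupling decay d = 6 nm.

The constants are a one-time calibration chosen so that (a) the peaks
sit near 600/720 nm, (b) RG(gap) is strictly decreasing on 0–30 nm, and
(c) the unbound/bound tether ensembles produce an RG contrast of the
experimentally observed size (~1.22 vs ~1.57 at 720/600 nm). The
surrogate preserves every qualitative contract the analysis uses; it
does not claim absolute cross sections. Simulated RG is evaluated at
720/600 nm, experimental RG at 709/585 nm (lamp-brightness optimum);
both pairs are configurable. Wavelength queries outside a spectrum's
grid are errors, never extrapolated.

## Ensemble analysis

Spectra are corrected as (raw − background)/excitation (bare-film
background, lamp normalization), clipped at zero. The calibration is
ordinary least squares of replicate-mean RG on **ln** concentration:
the natural-log axis is adopted because the experimentally printed line
(slope 0.106, intercept 0.902) reproduces the measured RG at 500 EU/ml
(1.561 vs 1.563) only under ln, not log₁₀; a `log_base` switch exists.
Zero-concentration blanks are excluded from the fit (log undefined) and
kept for blank-significance testing. The LOD is reported as a bracket:
(highest concentration not significantly different from blank, lowest
significantly different), with two-sided tests at α = 0.05. Group
statistics follow the experimental convention: pooled-variance
Student's t for two groups (Welch by flag), one-way ANOVA for three or
more. Activity-to-mass conversion uses 10 EU = 1 ng for this LPS
preparation.

## Single-particle analysis

Detection operates on the channel-summed image: Gaussian smoothing
(σ = 1 px), a robust global threshold (median + k·σ_robust with
σ_robust the normal-consistent MAD, default k = 5), and non-maximum
suppression at a minimum separation, followed by intensity-weighted
subpixel centroiding. Photometry uses a 3-px disk aperture with a 2-px
annulus whose per-channel median estimates the local background —
making the per-particle RG invariant to global gain and additive
offsets. Camera channels are used as-is (no spectral unmixing), so
camera RG and spectrometer RG are distinct scales and are never
cross-calibrated. Before/after frames are independent particle sets
(no tracking); the population shift is an unpaired t test. Spacing
statistics are per-point Euclidean nearest-neighbour distances.

## QCM analysis

Sauerbrey conversion mass = C·Δf/n with defaults C = 17.7 ng cm⁻² Hz⁻¹
(5-MHz AT-cut crystal), third-overtone raw frequency; all four crystal
constants are configuration. This is the unique standard combination
that reproduces the reported aptamer surface density (≈5.5×10¹²
molecules/cm² from the 33-Hz immobilization drop and the 66-mer's
molecular weight). Frequency drops are passed as magnitudes. Oligo
molecular weight uses the synthesis-vendor residue-mass convention
(per-base monophosphate masses, 5'-OH terminal correction, catalog
masses for the 5'-amino-C6 and 3'-thiol end modifications); the shipped
table is cross-checked in the tests against an independent
sequence-mass oracle up to the 5'-phosphate convention. Binding
kinetics are summarized as the OLS slope of Δf vs time over a labeled
interval, in Hz/min. Viscoelastic films violate Sauerbrey; a
dissipation-ratio check warns when ΔD/(Δf/n) exceeds a configurable
bound.

## Synthetic data

Generators mirror the four experimental data streams with full ground
truth:

- **Spectra**: two Lorentzians with the red amplitude solved in closed
  form so the noiseless RG at the evaluation pair equals the target;
  additive Gaussian noise.
- **Dark-field frames**: hard-core point process (dart throwing,
  minimum separation 0.35× the target spacing) whose intensity is
  calibrated — factor 0.91 on the Poisson spacing relation, measured
  once by direct simulation — so the mean nearest-neighbour spacing
  hits the target (default 3.6 μm); Gaussian PSF spots (σ = 1.5 px)
  whose red/green amplitude ratio realizes a drawn per-particle RG
  (blue = green, so RG = 1 is grayscale); Poisson shot noise plus
  Gaussian read noise. No Bayer/demosaicing or chromatic-aberration
  modeling.
- **Titrations**: RG = slope·ln C + intercept + N(0, σ), default six
  levels 15–500 EU/ml in triplicate with σ = 0.015, matching the
  experimental replicate scatter.
- **QCM traces**: back-to-back steps, each an exponential approach to
  its drop (normalized to complete exactly at the step end) plus a
  signed linear drift, so the zero-noise cumulative drop equals the sum
  of step magnitudes and a pure-drift step yields its slope exactly. A
  slow-binding event (e.g. a 3-Hz drop at −0.021 Hz/min) is generated
  as pure drift.

What passing closure tests show — and what they do not: every analyzer
recovers its generator's parameters under the stated noise, which
validates the algorithms and their statistical calibration. The
generators do not emulate particle-size dispersion, film roughness,
camera spectral response, viscoelastic QCM response, or matrix effects
of real samples, so closure on synthetic data does not by itself
establish accuracy on experimental recordings.

## Problem sizes and numerical choices

Default study conditions: 10⁵ Monte Carlo chains per state (bound
state pooled over 2/3/4-nm complex sizes), 10⁶ Brownian-dynamics steps
at Δt = 10⁻⁸ s, 0.25-nm histogram bins. The test suite runs reduced
sizes (10⁴ chains, 10⁵–10⁶ BD steps, 20–100 simulation seeds per
property) chosen so Monte Carlo error stays well inside each asserted
tolerance. Ties and degenerate inputs are rejected loudly rather than
guessed at: empty histograms, open LOD brackets, non-monotone
significance flags, zero-variance two-point groups, saturated frames
(warning), and non-positive green photometry are all explicit error
paths.

## Known limitations

- The scattering surrogate is qualitative; absolute spectra, particle-
  size dependence, and substrate dispersion are out of scope.
- The bound-state fold collapses the entire 36-nt binding region into
  one rigid rod; no sequence-dependent secondary structure.
- Only the gap coordinate is simulated (no x,y statistics, no
  rotational diffusion, no inertial dynamics).
- The bound-endotoxin surface density used in the bound-fraction
  statistic is an external input (the LPS molecular weight it assumes
  is not modeled here).
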