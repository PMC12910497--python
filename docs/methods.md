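# Methods

This note documents the models, conventions and parameter choices behind
each analysis chain, what the synthetic generators do and do not emulate,
and the known limitations.

## Droplet-pair geometry

Two adherent monolayer-coated droplets are treated as spheres truncated by
a planar bilayer. In the image plane each droplet projects to a circle; the
contact-patch radius `rc` is half the common chord of the two circles, the
bilayer area is `Ab = π rc²`, and the contact angle is defined per droplet
as the angle between the monolayer tangent at the contact line and the
bilayer plane, `θᵢ = arcsin(rc/Rᵢ)`, reported as the mean of the two. This
convention makes the tension balance `γ_b = 2 γ_m cos θ` return `2 γ_m` at
θ = 0 (fully separate monolayers) and 0 at θ = 90°.

Image detection thresholds (Otsu), labels connected components and fits
circles to subpixel marching-squares boundaries (Kåsa algebraic fit plus a
Gauss–Newton geometric refinement). An adherent pair projects to a *single*
component whose union boundary consists of exactly two circular arcs; it is
decomposed by alternating point-assignment/circle-fit iterations
(initialized by splitting the contour along its principal axis), which
converges because every boundary point lies on one of the two circles.
Separated pairs (two components) are fitted independently. Raster
convention: origin top-left, x rightward, y downward, lengths in px with a
user-supplied μm/px scale.

Droplets in permeability traces are treated as full spheres; the spherical-
cap volume correction is below 2% for the contact angles involved and is
exposed as the `cap_correction` config switch (off by default).

## Osmotic permeability

Flux law: `dV₁/dt = +Pf · Vw · A · (c₁ − c₂)`, `dV₂/dt = −dV₁/dt`, with
`Vw = 18.05 cm³/mol` (water near 30 °C) and `cᵢ = nᵢ/Vᵢ` the osmolar
concentrations of an impermeant solute. Units are carried so that Pf
emerges in μm/s from μm-scale volumes and areas. Osmolality (mOsm/kg) is
converted to osmolarity assuming solution density 1.0 kg/L; the default
gradient of 186 mOsm/kg corresponds to 0.1 M NaCl (ideal van 't Hoff factor
2 corrected by a 0.93 osmotic coefficient) and is overridable wherever it
appears, since a measured osmolality is always preferable. Droplet 1 is by
convention the hyperosmotic droplet and swells.

Integration uses adaptive Runge–Kutta (rtol 1e-8) with a termination event
reporting the depletion time if a droplet empties. The bilayer area is held
at its initial value during fitting (observation windows are short); the
`dynamic_area` option recomputes `A` at constant contact angle instead.

Estimation: `initial_rate` fits a line to V₁(t) over the first 10% of
frames (at least 10) and divides the slope by `Vw·A·Δc₀`; `ode_fit`
(default) runs bounded least squares (Pf ∈ (0, 10⁴] μm/s) of the forward
model against both diameter traces, started from the initial-rate estimate
(falling back to a full-trace slope when the short window is noise-
dominated). The reported standard error comes from the Gauss–Newton
Jacobian; the relative rms diameter residual is the fit diagnostic.

## Tensiometry

`γ_b = 2 γ_m cos θ` with θ in degrees externally. Report tables round γ_b
to 2 decimals. First-order uncertainty propagation
(`σ² = (2cosθ·σγm)² + (2γm sinθ·σθ)²`) is provided but optional, since
replicate SDs are the primary uncertainty in practice. Control-relative
tensions divide by the 0 mM record of the same membrane; exactly one
control per membrane is required.

## DSC reduction

The main transition is reduced to `Tm` (argmax of the excess heat capacity
with parabolic refinement over three points), `ΔH` (trapezoidal integral
over the peak support) and fwhm (interpolated half-height crossings). Peak
location, crossings and support are read off a Savitzky–Golay-smoothed
trace (order 2, window ≈ fwhm/3 — unbiased for the quadratic peak top) so
replicate noise cannot spoof crossings; the integral itself uses the raw
corrected trace. The support is the contiguous region above 1% of peak
height, extended outward to the nearest zero crossings. A peak must exceed
5× the flank standard deviation and lie away from the scan-window edges.

Baseline: the default jointly fits a pseudo-Voigt transition plus a linear
baseline and subtracts only the baseline part. Flank-interpolated baselines
(the classical sigmoidal/linear constructions, both retained as options)
sit on top of the transition's tails and were measured here to clip 1–4% of
the enthalpy of broad or tailed endotherms — more than the reduction
pipeline's own error budget — which is why the fitted baseline is the
default. Cooling scans are sign-flipped before analysis. Temperature grids
need not be uniform; all integrals are trapezoidal. Enthalpy is normalized
per mole of total lipid (not per mole of the majority component), flagged
in the metadata.

## Raman analysis

Preprocessing subtracts a degree-3 polynomial baseline fitted to non-peak
regions, identified by iteratively refitting on points at or below the
current fit (modpoly-style), clips negative residuals and rescales so the
2840–2860 cm⁻¹ maximum equals 1. Serotonin's own scattering is removed by
subtracting the reference spectrum scaled so its ~1540 cm⁻¹ indole band
matches the sample's; the negative-residual mass after subtraction is kept
as a QC metric. Band intensities are windowed maxima over ±10 cm⁻¹ around
2850/2890/2930 cm⁻¹ — maxima are robust on normalized spectra, and the
band centers are only approximate; a pseudo-Voigt peak-height fit is
available behind `band_method="voigt"`. All ratios are invariant to global
intensity scaling by construction.

## Statistics

Balanced membrane × concentration tables use the classical closed-form
fixed-effects decomposition (main effects, interaction, residual), which
sums exactly to the total SS and is fast enough for 10⁴-table null
calibrations; unbalanced tables fall back to Type-II SS via OLS with a
warning. Tukey HSD uses the Tukey–Kramer statistic with the pooled ANOVA
residual mean square; the studentized-range CDF is evaluated in-package by
nested Gauss–Legendre quadrature (64 nodes; scale variable integrated over
the effective support of √(χ²_ν/ν)), accurate to ~1e-9 against independent
implementations. Significance stars follow the 0.05/0.01/0.001/0.0001
convention. Control-normalized summaries divide by the control mean; the
control's error bar is the relative SD of the raw control replicates prior
to normalization.

## Synthetic generators

All generators are pure functions of (parameters, seed) and store their
ground truth in metadata; round-trip recovery is the universal test
pattern. Dose responses saturate as `effect = emax · c/(c + c50)` with
`c50 = 10 mM`, mimicking the observed leveling-off at high dose; `emax` per
membrane and observable is set so the 40 mM condition matches the observed
high-dose changes (control levels: Pf 73/62/67 μm/s; Tm −16.68/−15.88/
−18.67 °C; ΔH 8.34/9.10/2.67 kcal/mol; fwhm 1.50/0.95/2.73 °C for DOPC,
DOPC/DOPS and DOPC/SM/Chol). These are illustrative generator settings,
not estimated quantities; the DOPC/DOPS tensiometry controls are
interpolated since that assay covered only two membranes.

Specifics:

* droplet traces: forward simulation at the condition's Pf, 100 μm
  droplets, 186 mOsm/kg gradient, 1 s frames for 60 s, multiplicative
  radius noise (default 0.5%);
* thermograms: a single pseudo-Voigt endotherm with Lorentz fraction
  η = 0.15 (lipid main transitions are close to Gaussian, with slight
  tails) on a gentle linear baseline, grid −40…−5 °C at 0.02 °C, noise SD
  0.5% of peak height;
* Raman: Gaussian bands (fwhm 12 cm⁻¹) at 2850/2890/2930 cm⁻¹ whose
  heights drive I2930/I2890 up with dose, plus a dose-scaled serotonin
  spectrum (1540 cm⁻¹ indole band and aromatic C–H contributions) on a
  sloped baseline, grid 1400–3100 cm⁻¹;
* study tables: 3 membranes × 6 doses with replicate noise (3.5% for Pf,
  3–4% for the others, Tm additive 0.08 °C); 3 replicates by default
  matching the calorimetry/Raman sample counts, while permeability
  analyses pool ≥50 runs per condition as in the DIB assay;
* images: antialiased disks (1 px edge ramp) with additive Gaussian noise.

What the generators do **not** emulate: instrument artifacts (CCD spikes,
DSC scan-rate hysteresis, unstirred layers), drift within a measurement
series, solute permeation, and domain (lo/ld) structure — Raman here is a
bulk measurement by construction. Passing tests therefore demonstrate the
correctness and calibration of the analysis chains on data obeying the
stated models, not the hardware-specific behavior of any instrument.

## Numerical choices and degenerate inputs

Tolerances: ODE rtol 1e-8; least-squares xtol/ftol 1e-12; quadrature 64
nodes. Tie-breaks: the droplet detector orders circles largest-first; the
transition analyzer takes the global argmax (a 10:1 mixture reports the
dominant component). Degenerate inputs raise typed errors: disjoint/nested
circles (`NoBilayerError`), blank or >2-component frames
(`UnusableFrameError`), flat traces under a nonzero gradient or negative
fitted Pf (`MeasurementError`), missing controls, peaks at window edges or
below 5σ (`NoTransitionError`), spectra without the 2850 or 1540 cm⁻¹
anchor bands (`UnusableSpectrumError`).

## Known limitations

* The contact-angle convention (arcsin(rc/R), averaged) is a documented
  assumption; alternative conventions shift θ by fractions of a degree.
* The enthalpy of strongly Lorentzian peaks is underestimated by the
  fraction of tail area outside the scan window (~0.5% at fwhm 1.5 °C,
  ~2% at fwhm 6 °C in a 35 °C window); no extrapolation is attempted.
* Osmolality→osmolarity conversion assumes unit solution density; at
  0.1 M NaCl the bias is <1%.
* The Tukey quadrature loses accuracy below ~3 residual degrees of
  freedom; the studies of interest have ≥12.
* Problem sizes in the tests (60-frame traces, 1751-point thermograms,
  200-configuration recovery sweeps, 10⁴-table null calibrations) were
  chosen to exercise each estimator's asymptotics while keeping the suite
  quick to run.
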