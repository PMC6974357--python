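# Methods

## Hyperspectral pigment mapping

**Reflectance calibration.** Raw stacks are dark-corrected (elementwise
subtraction, clipped at zero counts) and normalized to % reflectance
against a dark-corrected stack of a calibrated reflectance standard
(default 20%). The standard stack is collapsed to a single per-wavelength
reference spectrum by spatial averaging before division: the standard is
imaged separately from the sample, so a per-pixel division would pair
unrelated pixels. Wavelengths where the reference is zero are masked with a
warning rather than propagated as infinities.

**Fourth-derivative spectroscopy.** Per-pixel spectral fourth derivatives
are computed by Savitzky–Golay filtering (`scipy.signal.savgol_filter`,
`deriv=4`), which fits a local polynomial and differentiates it
analytically. Two properties make this the right estimator here and are
enforced by tests: it annihilates every spectrum that is a polynomial of
degree ≤ 3 exactly (smooth scattering baselines vanish), and on grids that
resolve a Gaussian dip it reproduces the closed-form fourth derivative.
A uniform wavelength grid is required (mean spacing used; >1% spacing
variation is rejected). Half a window of edge bands is masked on each side.

**Sign convention.** For an absorption dip — a negative Gaussian riding on
the reflectance baseline — the fourth derivative at the dip center is
*negative* (d⁴/dx⁴[−e^(−x²/2σ²)] = −3/σ⁴ at x = 0), flanked by positive
lobes. Band amplitudes are therefore the per-pixel maximum of the *negated*
fourth derivative within the band, floored at zero: this statistic peaks
exactly at the dip center, is strictly linear in dip depth, and keeps
"extent of light attenuation" nonnegative. The maximum (rather than a band
mean or integral) is robust to band-edge snapping on coarse grids; a mean
variant is available.

**Filter window.** Default window 25 bands, polynomial order 5, both
configurable. The window was chosen from the noise budget of the deriv-4
filter: at a 2-nm grid, a 9-band window has a white-noise gain of ~0.02 per
unit σ against a chlorophyll-f signal amplitude of ~0.006 per unit dip
depth, drowning the band map at realistic noise; a 25-band window cuts the
noise gain two orders of magnitude while retaining exact cubic
annihilation, exact rank recovery of abundance fields, and ~35× separation
between the 670–680 and 718–722 nm band maps. The trade-off is attenuation
of narrow-dip amplitudes (they remain linear in depth, so relative maps and
rankings are unaffected) and a wider masked edge.

**Abundance scaling.** Band maps are linearly rescaled so the 99.5th
percentile maps to 1 (values above saturate), guarding against hot pixels.
An all-zero map stays zero. The scaling is per-image; cross-panel
comparability therefore holds only within one image.

**Overlays.** Binary mode paints Chl *a* detections green and Chl *f*
detections red, with red taking precedence where both exceed threshold
(far-red patches sit inside a Chl-*a*-rich matrix and must stay visible);
continuous mode blends a colormapped 0–1 Chl *f* abundance. ROI spectra are
means ± population SD per wavelength. The same band-map machinery renders
confocal emission stacks (phycobiliprotein 650–660, Chl *a* 690–700,
Chl *f* 740–750 nm) as false-color composites.

## Ratiometric O₂ imaging

**Model.** The sensor paint's O₂-quenched red emission over a constant
green reference gives R = red/green decaying with O₂; referencing to the
dark-anoxic state, ΔR = R_dark − R, yields the single-exponential
saturation ΔR(C) = a·(1 − e^(−b·C)) with ΔR(0) = 0 by construction — the
simplest family consistent with an exponential R(C) decay and an anoxic
reference. Two-site quenching models are out of scope. ΔR referencing also
cancels time-constant additive red backgrounds such as chlorophyll
autofluorescence. The blue channel is unused by the sensor chemistry.

**Calibration.** The fit is ROI-mean ΔR versus known bulk O₂
(nonlinear least squares, `scipy.optimize.curve_fit`, positivity bounds;
initialization a₀ slightly above max ΔR, b₀ from inverting the model at
the highest-O₂ point). At least 3 points spanning ≥ 2 levels including a
(near-)anoxic one are required. Per-pixel calibration is deliberately not
the default: the calibration target is a separately coated slide.

**Inversion.** C = −ln(1 − ΔR/a)/b per pixel, with ΔR clamped into
[0, a(1 − 10⁻⁶)] (clamped pixels flagged) and C capped at 150% air
saturation. Pixels with green signal below 1% of the channel's dynamic
range are masked before ratioing; masks only grow along the pipeline.

**Dark-anoxic reference.** Mean of ratio images recorded in darkness at
t ≥ 45 min, restricted (via `before_t`) to frames before the first
illumination — dark frames recorded *after* a light period still carry
decaying O₂ and would bias the reference.

**Units.** % air saturation converts to µmol O₂ L⁻¹ with the
Garcia–Gordon (1992) combined-fit solubility (Benson–Krause scale,
µmol kg⁻¹; verified against the published check value 274.61 µmol kg⁻¹ at
10 °C, S = 35) times EOS-80 surface density. Default conditions 23 °C,
salinity 35, overridable.

## Rates and areal scale-up

Rates are finite differences of O₂ concentration across a light
transition: the last frame at or before the event minus-wise against the
first frame after it, Δt from actual timestamps (nominally 5 min). Rates
are signed d[O₂]/dt — consumption negative; R_D warns if its median is
positive. P_N defaults to the transition bracket; a `max` mode takes the
per-pixel maximum rate over the light period instead. P_G = P_N + |R_D|
pixelwise, exact by construction. ROI summaries use the population SD
(divide by n) as a descriptive within-ROI spread.

The areal scale-up keeps the factored unit chain
rate × porosity × thickness_cm × 10⁻⁶ × 10⁴ × 60 (µmol L⁻¹ min⁻¹ ≡
nmol cm⁻³ min⁻¹; cm²→m²; min→h) exactly in this form so the worked example
10 × 0.4 × 0.1 → 0.24 mmol O₂ m⁻² h⁻¹ is bit-reproducible, and the NIR
share of a 10 mmol O₂ m⁻² h⁻¹ total is 2.4%.

## Synthetic scenes

**Hyperspectral.** Reflectance is a degree-≤3 polynomial baseline
(optionally plus a broad Gaussian) multiplied by Gaussian dips,
R(λ,x,y) = B(λ)·∏(1 − Aᵢ(x,y)Gᵢ(λ)); raw counts are rebuilt through the
acquisition model (smooth lamp spectrum, 20% standard, dark offset,
additive Gaussian noise in % reflectance units). Defaults emulate the
target habitat: a Chl *a* dip (675 nm, σ 8 nm, depth 0.6) in a surface
layer occupying the top quarter of the image, and Chl *f* dips (720 nm,
σ 8 nm, depth 0.4) in three Gaussian hotspots (σ 5 px) at 40–80% depth;
400–850 nm at 2 nm steps, 64 × 64 px.

**Optode.** O₂ relaxes pixel-locally toward a steady-state field after
light-on and back to anoxia after light-off, C(t) = C_ss(1 − e^(−t′/τ)) /
C_off·e^(−t′/τ), with τ = 5 min and hotspot C_ss = 50% air saturation —
reproducing the observed dynamics (hotspots from 0 to 40–50% air
saturation within 15–20 min; dissipation within minutes of darkening).
The camera model is red = G₀(a·e^(−bC) + r_inf) + ε, green = G₀ + ε, the
exact forward model of the calibration family, with a = 1.5 and b = 0.02
per % air sat so the sensor stays sensitive across 0–100% air saturation
(ΔR at 100% ≈ 86% of the asymptote), as for typical indicator/reference
paints. Additive Gaussian camera noise; SNR = G₀/σ. Frames every 5 min:
dark 0–50 min (the ≥ 45-min anoxic reference window), light 50–80 min,
dark to 110 min. A `ramp` mode substitutes linear ramps (piecewise-constant
true rates) for exactness tests.

**Exported truth.** Per frame: the O₂ field and the instantaneous rate
dC/dt. Per event: the bracket-mean rate (C_after − C_before)/Δt — the
quantity the finite-difference estimator actually targets. With τ = Δt =
5 min the bracket average is ~37% below the instantaneous initial slope
C_ss/τ; recovery tests compare against the bracket truth (the estimator's
estimand), and a separate test pins the analytic relation between the two.

**What the generator does not emulate.** No lateral O₂ diffusion (so
analytic truth exists; real agar-layer measurements are diffusionally
smeared and underestimate true rates), no realistic rock texture or
spectral mixing beyond multiplicative dips, no flat-field or vignetting
effects, symmetric light/dark kinetics (which makes synthetic P_G ≈ 2·P_N,
somewhat above field-observed gross rates of ~5–15 µmol O₂ L⁻¹ min⁻¹), and
additive rather than true Poisson shot noise. Passing tests therefore
demonstrate correctness of the estimators under the stated forward models,
not robustness to these real-data effects.

## Numerical choices and degenerate inputs

- Wavelength snapping: nearest sampled band within 5 nm, lower wavelength
  wins exact ties; band windows snap endpoints to sampled wavelengths,
  inclusive.
- Coordinates 0-based (row, col), origin top-left; ROI masks are
  same-shape boolean images or labeled integer images (0 = background).
- All-zero abundance maps normalize to all-zero (no division by zero);
  empty or fully masked ROIs raise; missing bracketing frames raise naming
  the event time.
- Calibration fit failures (non-convergence, non-positive parameters)
  raise a dedicated error with the offending values.
- Reflectance values above 100% are permitted but flag the cube
  (`overrange`), as specular glints can exceed the standard.

## Problem sizes

Default test and reproduction scenes are 64 × 64 px × 226 bands and
48 × 64 px × 23 frames — small enough that the full suite runs in seconds
while every code path (calibration, filtering, inversion, rates, I/O, CLI)
is exercised end-to-end; all statistics scale per-pixel, so conclusions do
not depend on image size.
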