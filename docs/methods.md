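# Methods

## Forward model

Tissue reflectance under spatially modulated illumination is modelled with
the standard diffusion approximation for a semi-infinite homogeneous
medium. With µtr = µa + µ′s, reduced albedo a′ = µ′s/µtr, and a
frequency-shifted effective attenuation µ′eff(fx) = √(3µaµtr + (2πfx)²),

    Rd(fx) = 3 A a′ / ((µ′eff/µtr + 1)(µ′eff/µtr + 3A)),

where A = (1−R_eff)/(2(1+R_eff)) and R_eff ≈ 0.0636n + 0.668 + 0.710/n −
1.440/n² accounts for the refractive-index mismatch (n = 1.4 by default).
This closed form stands in for a Monte Carlo photon-transport table: it is
deterministic, desk-scale, and accurate enough over the working range
(µa 0.005–0.05 mm⁻¹, µ′s 0.5–3 mm⁻¹, fx ≤ 0.2 mm⁻¹). The lookup-table
interface records a `forward_model_id`, so an externally computed Monte
Carlo surface with the same schema can be swapped in without touching the
inversion code.

One caveat of the closed form: at fx = 0.2 mm⁻¹ the (2πfx)² term dominates
3µaµtr, and near the low-scattering edge of the range R_AC is no longer
strictly decreasing in µa — it can rise by about 1e-4 relative between
neighbouring grid nodes. This does not fold the 2-D map (R_DC remains
strictly monotone and pins the inverse), so `build_lut` enforces strict
monotonicity on R_DC and tolerates up to 1e-3 relative upward wiggle on
R_AC before failing.

## Rendering conventions

A pattern at spatial frequency fx > 0 produces frames

    I = G · [Rd(0) + Rd(fx) · cos(2π fx x + φ + Δφ_h)] / 2,

so the fringe amplitude carries the AC reflectance at half scale and the
offset carries the planar reflectance at half scale. A pattern at fx = 0 is
uniform illumination, I = G·Rd(0): the three "phase" frames of the planar
stack are identical up to noise. These conventions cancel in calibration
(sample and phantom share them) and are accounted for explicitly in
single-snapshot demodulation (low-pass channel ×2).

The gain G contains the illumination level and two height effects:

- a Lambertian tilt factor cos θ = 1/√(1+|∇h|²) — a tilted surface element
  intercepts less irradiance;
- optionally an inverse-square working-distance factor (d₀/(d₀−h))²,
  disabled by default (at the 450 mm working distance and ≤ 20 mm relief it
  is a ≤ 9% effect, and keeping the default model minimal makes the
  correction stage's identity property exact).

Height also shifts the fringe phase by Δφ_h = 2π fx h tan θ_tri with a
default triangulation angle of 15° — the standard crossed-axis
fringe-projection geometry. The profilometry stage inverts exactly this
pair of effects, by design: the correction model is only ever as good as
the renderer it mirrors, and real-instrument angular response calibration
is out of scope.

Default noise is additive Gaussian read noise at σ = 0.5% of the unit full
scale, applied per frame; Poisson shot noise is available. All randomness
derives from a single acquisition seed.

## Scene and study defaults

The instrument geometry follows the described system: 1,024 × 1,280 px
over a 15 × 15 cm field of view (pixel pitch 150/1280 ≈ 0.117 mm), with a
quarter-resolution 256 × 320 default for tests and demos (≈ 30 fringe
periods across the field at fx = 0.2 mm⁻¹; full resolution by flag).

Liver scenes are three column bands (LL | LM | RM) with StO₂ constant
inside each lobe mask and smooth (smoothstep) transitions confined to the
gaps between masks, so lobe-mask means equal their targets exactly. The
demarcation band between the left territory (LL+LM) and RM defaults to
4 mm wide for total inflow occlusion (a sharp line) and 14 mm for
arterial-only occlusion (a faint, broad transition); its detection score —
the median |∇StO₂| along the segmented territory boundary — orders the two
accordingly.

Chromophore defaults: baseline total hemoglobin and scattering of pig
liver are not published for this system, so placeholders are used and
documented as such — total hemoglobin 40 µM (chosen so that µa stays inside
the lookup range at both wavelengths for StO₂ from 0 to ~90%), µ′s = 1.6
mm⁻¹ at 665 nm and 1.2 mm⁻¹ at 860 nm (generic soft tissue, scattering
falling with wavelength). Molar extinction coefficients at 665/860 nm are
interpolated and rounded from the standard hemoglobin compilation (Prahl,
OMLC) and shipped as a versioned CSV; the red channel is deoxy-dominant and
the NIR channel oxy-dominant, which keeps the 2×2 unmixing system well
conditioned. Because the same table is used for generation and unmixing,
round trips are exact regardless of compilation fidelity.

The study simulator draws per-animal values around the reported group
means/SDs (n = 6 per group; reperfusion cells reuse baseline values, as
saturation returned promptly to baseline after declamping). Lactate and
the reference-oximeter value inherit a linear share of the same animal's
StO₂ deviation, with residual noise sized so each cell's total SD matches
its specification; the coupling coefficients (−0.281 mmol/L per StO₂ point
for lactate, +0.281 pp/pp for the reference) were calibrated once by
bisection on the Monte Carlo mean of the pooled sample correlation, to
targets of −0.76 and +0.82 respectively. `calibrate_coupling` re-runs that
procedure for other designs. The per-cell coupling is capped where a
cell's SD would be exceeded (e.g. baseline lactate SD 0.4 mmol/L against
StO₂ SD 7.7), so the realized within-cell correlation saturates there.

What the generator does *not* emulate: spatial texture and vascular
structure within lobes, specular reflections (the instrument rejects them
with crossed polarizers), lens distortion, inter-animal anatomical
variation in the images, and motion. Passing tests therefore demonstrate
the correctness of the computation under the stated acquisition model, not
robustness to those real-world effects.

## Numerical choices

- **Three-phase demodulation** is the exact trigonometric identity; it is
  tested to machine precision on noiseless renders. A common global phase
  offset in the three projector phases is tolerated (it shifts only the
  fringe phase); the steps themselves must be 2π/3.
- **Single-snapshot filters**: raised-cosine windows, low-pass cutoff fx/2
  around zero frequency and a band-pass disc of radius fx/2 centred on the
  +fx carrier (single sideband; a full annulus would mix both sidebands and
  break envelope extraction). Roll-off spans the outer 50% of each window
  radius. Frames are symmetrically padded by one filter width before the
  FFT and a border of 1.5 filter widths is flagged invalid — mirror padding
  reverses the fringe direction at the boundary and its transient extends
  slightly past one width.
- **Phase unwrapping** uses a quality-guided 2-D unwrapper; the global
  2π-multiple ambiguity is resolved by assuming the median scene height is
  within half a fringe equivalent (≈ 9 mm at the defaults) of the reference
  plane. Scenes with no pixel at the reference height violate this and
  need an explicit reference offset.
- **Lookup-table inversion**: µa log-spaced (relative absorption accuracy
  drives StO₂ accuracy), µ′s linear, 128 points each; inversion
  precomputes µa(R_DC, R_AC) and µ′s(R_DC, R_AC) on a 512² raster by
  scattered linear interpolation of the forward samples, then looks pixels
  up bilinearly. Out-of-hull pixels are masked invalid, never clamped —
  silent clamping would corrupt StO₂ downstream. Round-trip error over the
  interior of the range is ≲ 0.02%.
- **Phantom reference processing**: the homogeneous flat phantom's true
  modulation is spatially smooth, so its measured maps are Gaussian
  low-pass filtered (σ = 8 px) before calibration. Without this, the
  phantom's own read noise is injected into every calibrated image,
  roughly doubling the per-pixel reflectance variance; at deeply
  desaturated pixels that variance feeds a noticeable positive Jensen-type
  bias in the StO₂ ratio. Smoothing leaves slowly varying illumination
  gain (which the calibration ratio must cancel) intact.
- **Unmixing**: negative concentrations from the linear solve are clipped
  to zero and flagged `clipped` rather than masked — this preserves the
  spatial continuity of StO₂ maps near the noise floor while keeping QC
  visibility. Pixels with total hemoglobin below 1 µM are masked (StO₂
  undefined). ROI statistics use valid, unclipped pixels.
- **ANOVA comparisons**: two-factor ANOVA (lobe × timepoint, with
  interaction) via OLS; pairwise timepoint comparisons within each lobe use
  the pooled residual mean square, with Šidák adjustment over the whole
  family (the adjustment method of the original analysis is unnamed; Šidák
  is a common default of the named software and is exposed in
  configuration). Factor levels are processed in sorted order so results
  are invariant to row order. A constant response returns F = 0, p = 1 by
  convention.
- **Correlations** pool all (animal, lobe, timepoint) rows across both
  groups by default, with a per-group option — whether the original pooled
  across groups is unstated, so neither mode is claimed as "the"
  computation.

## Problem sizes

Tests and demos run at quarter resolution (256 × 320); the full
1,024 × 1,280 geometry is available via `PipelineConfig(resolution="full")`.
The significance-pattern check uses 500 replicate studies; correlation
calibration checks use 1,000. These sizes were chosen as the package's
standard verification configuration.

## Known limitations

- The diffusion approximation under-represents high-frequency, low-albedo
  reflectance compared with transport-accurate models; accuracy claims are
  relative to the package's own forward model.
- The deep-learning demodulation and profilometry networks of the
  real-time instrument are out of scope; the classical algorithms they
  replaced are the implemented contract.
- The profilometry correction model is the renderer's inverse; it does not
  calibrate a real instrument's angular response.
- Two chromophores at two wavelengths: water, fat and melanin are
  neglected, and no baseline absorption offset is applied.
- StO₂ lobe means at very low saturation (< 10%) retain a small positive
  bias (≈ +1 pp at default noise) from the nonlinearity of the
  concentration ratio under per-pixel noise; it shrinks quadratically with
  the noise level.
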