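# ssoptk

Structured-light tissue oxygenation imaging — a spatial frequency domain
imaging (SFDI) / single snapshot imaging of optical properties (SSOP)
processing pipeline, exercised entirely on synthetic scenes of a
hemi-hepatic ischemia experiment in swine.

## The problem

During liver resection, surgeons rely on the ischemic *demarcation line*
to guide transection, but visual assessment is subjective. Structured-light
oximetry offers a contrast-free, quantitative alternative: sinusoidal
patterns at two spatial frequencies (fx = 0 and 0.2 mm⁻¹) and two
wavelengths (665 and 860 nm) are projected onto the tissue, and the
spatially modulated diffuse reflectance encodes the absorption µa and
reduced scattering µ′s of the tissue, from which oxy-/deoxy-hemoglobin
concentrations and the oxygen saturation StO₂ follow.

This package implements that computation as a tested library, plus the
synthetic counterpart of the animal experiment it was used in: two occlusion
models — total vascular inflow occlusion (TVIO) and hepatic artery occlusion
(HAO) — measured on three liver lobes (LL, LM, RM) at baseline (T0),
ischemia (T1) and reperfusion (T2).

## The method

1. **Demodulation.** Three frames phase-stepped by 2π/3 give the planar
   (M_DC) and modulated (M_AC) amplitudes exactly:
   M_AC = (√2/3)·√((I₁−I₂)² + (I₂−I₃)² + (I₃−I₁)²). The single-snapshot
   (SSOP) route recovers both from one high-frequency frame by Fourier
   filtering, enabling video-rate imaging.
2. **Calibration.** A phantom with known (µa, µ′s) converts modulation to
   diffuse reflectance: R = (M_sample/M_phantom)·Rd_model, cancelling the
   illumination gain.
3. **Inversion.** A lookup table of the diffusion-approximation forward
   model Rd(µa, µ′s, fx) over µa ∈ [0.005, 0.05] mm⁻¹, µ′s ∈ [0.5, 3] mm⁻¹
   is inverted per pixel from the (R_DC, R_AC) pair.
4. **Profilometry.** The fringe phase (φ = atan2(√3(I₃−I₂), 2I₁−I₂−I₃))
   yields the surface height h = Δφ/(2π fx tan θ); dividing the modulation
   by the modelled Lambertian tilt factor removes the intensity bias of
   curved surfaces.
5. **Oxygenation.** Beer–Lambert unmixing of the two µa maps:
   µa(λ) = ln10·(ε_HbO₂(λ)C_HbO₂ + ε_Hb(λ)C_Hb), StO₂ = 100·C_HbO₂/(C_HbO₂+C_Hb).
6. **Statistics.** Lobe×timepoint two-way ANOVA with Šidák-adjusted
   pairwise comparisons, Pearson correlation matrix (StO₂, lactate,
   reference oximeter), and demarcation-line detection/sharpness scoring.

The synthetic generators close the loop: a forward renderer produces frame
stacks from ground-truth scenes (including height-dependent fringe shift
and tilt shading), and a study simulator draws lobe-level tables around the
reported group statistics with a calibrated StO₂–lactate coupling.

## Worked example

```bash
ssoptk run --demo tvio --seed 1 --outdir demo_tvio
```

renders the three-timepoint TVIO experiment at quarter resolution
(256×320), runs the full pipeline and prints the recovered lobe time
course:

```
roi timepoint  mean_sto2  sd_sto2  n_pixels  empty
 LL        T0  45.921027 3.622129     24576  False
 LM        T0  42.624840 3.741912     19712  False
 RM        T0  47.938753 3.526598     24576  False
 LL        T1  16.149350 4.738739     24562  False
 LM        T1   7.332558 4.100452     17652  False
 RM        T1  43.106046 3.763983     24576  False
 LL        T2  45.888400 3.602523     24576  False
 LM        T2  42.581511 3.774725     19712  False
 RM        T2  47.907426 3.534349     24576  False
```

The left lobes desaturate deeply under total inflow occlusion
(LL 45.9 → 16.1%, a 29.8-point drop; ground truth 46.0 → 16.2%), the right
lobe barely changes, and reperfusion returns to baseline — recovered through
the complete render → demodulate → calibrate → profile-correct → invert →
unmix chain at the default 0.5% sensor read noise. `demo_tvio/` also holds
the StO₂ maps (TIFF), the simulated study table, ANOVA comparisons,
correlations and a provenance manifest.

Other entry points: `ssoptk simulate | demodulate | calibrate | invert |
oxygenate | stats | demarcation`, each a thin wrapper over the library
(`import ssoptk`).

## Layout

- `src/ssoptk/forward.py` — diffusion-approximation reflectance, Beer–Lambert absorption
- `src/ssoptk/scenes.py` — scene specs, liver scenes, structured-light renderer
- `src/ssoptk/study.py` — study-table simulator and coupling calibration
- `src/ssoptk/demodulation.py` — three-phase and single-snapshot demodulation, phase extraction
- `src/ssoptk/calibration.py` — phantom calibration to reflectance
- `src/ssoptk/inversion.py` — lookup-table build and per-pixel inversion
- `src/ssoptk/profilometry.py` — phase-to-height and tilt-intensity correction
- `src/ssoptk/oxygenation.py` — hemoglobin unmixing, StO₂ maps, ROI time courses
- `src/ssoptk/analysis.py` — ANOVA, correlations, demarcation detection
- `src/ssoptk/pipeline.py`, `cli.py`, `io.py` — orchestration, CLI, file formats

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
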