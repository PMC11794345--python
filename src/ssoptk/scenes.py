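"""Synthetic structured-illumination scenes of a hemi-hepatic ischemia model.

A scene holds per-pixel ground truth (hemoglobin concentrations, reduced
scattering, surface height) plus named lobe masks for the three liver lobes
of the swine model: left lateral (LL), left medial (LM) and right medial
(RM).  The renderer projects sinusoidal patterns at the configured spatial
frequencies/phases and produces the camera frame stack a structured-light
oximeter would acquire, using the diffusion forward model for tissue
reflectance, a Lambertian surface-tilt intensity factor, and a
fringe-projection phase shift proportional to surface height.

Rendering convention: a pattern at fx = 0 is uniform illumination, so the
three "phase" frames of the planar stack are identical up to noise; for
fx > 0 each frame is

    I = G * [Rd(0) + Rd(fx) * cos(2 pi fx X + phi + dphi_h)] / 2

with G the illumination gain (including the Lambertian cos(theta) factor)
and dphi_h = 2 pi fx h tan(theta_triangulation) the height-induced fringe
shift.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .forward import diffuse_reflectance_forward, mu_a_from_chromophores
from .oxygenation import ExtinctionTable, load_extinction_table
from .study import PRINTED_CELL_STATS, GROUPS, LOBES, TIMEPOINTS

# Paper-scale acquisition geometry: 1,024 x 1,280 px over a 15 x 15 cm
# field of view. Pixel pitch is set by the 1,280-px horizontal axis.
FULL_SHAPE = (1024, 1280)
QUARTER_SHAPE = (256, 320)
FOV_WIDTH_MM = 150.0

DEFAULT_WAVELENGTHS = (665, 860)
DEFAULT_SPATIAL_FREQUENCIES = (0.0, 0.2)  # mm^-1
DEFAULT_PHASES = (0.0, 2.0 * np.pi / 3.0, 4.0 * np.pi / 3.0)

#: Default total hemoglobin (mol/L). Pig-liver baseline values are not
#: published for this system; 40 uM keeps mu_a at both wavelengths inside
#: the inversion table's 0.005-0.05 mm^-1 range for StO2 from 0 to ~90%.
DEFAULT_TOTAL_HB = 40e-6

#: Default reduced scattering per wavelength (mm^-1), generic soft-tissue
#: values inside the 0.5-3 mm^-1 table range (scattering falls with
#: wavelength).
DEFAULT_MU_S = {665: 1.6, 860: 1.2}

# Lobe layout as column fractions: LL | ramp | LM | demarcation gap | RM.
_LL_END = 0.30
_LM_START = 0.34
_LM_END = 0.58
_RM_START = 0.70
_DEMARCATION_CENTER = 0.64

#: Demarcation transition-band width (mm): total inflow occlusion yields a
#: sharp line, arterial-only occlusion a broad, faint one.
DEMARCATION_WIDTH_MM = {"TVIO": 4.0, "HAO": 14.0}


def pixel_pitch_for(shape: tuple[int, int]) -> float:
    """mm per pixel for a sensor spanning the standard field of view."""
    return FOV_WIDTH_MM / shape[1]


# ---------------------------------------------------------------------------
# Height-map helpers
# ---------------------------------------------------------------------------

def flat_height(shape: tuple[int, int]) -> np.ndarray:
    return np.zeros(shape, dtype=float)


def gaussian_bump_height(
    shape: tuple[int, int],
    pixel_pitch: float,
    peak_mm: float = 20.0,
    sigma_mm: float = 25.0,
    center: tuple[float, float] | None = None,
) -> np.ndarray:
    """Isolated Gaussian elevation, zero at the borders."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = center if center is not None else (h / 2.0, w / 2.0)
    r2 = ((yy - cy) ** 2 + (xx - cx) ** 2) * pixel_pitch**2
    return peak_mm * np.exp(-r2 / (2.0 * sigma_mm**2))


def tilted_plane_height(
    shape: tuple[int, int],
    pixel_pitch: float,
    slope_x: float = 0.2,
    slope_y: float = 0.0,
) -> np.ndarray:
    """Plane h = slope_x * x + slope_y * y (mm per mm slopes), zero-mean."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    plane = slope_x * xx * pixel_pitch + slope_y * yy * pixel_pitch
    return plane - plane.mean()


def lobe_dome_height(
    shape: tuple[int, int], pixel_pitch: float, peak_mm: float = 15.0
) -> np.ndarray:
    """Broad dome emulating the curved liver surface (non-zero slopes over
    most of the field, gentle enough for the Lambertian model)."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    ry = (yy - h / 2.0) / (h / 1.6)
    rx = (xx - w / 2.0) / (w / 1.6)
    r2 = rx**2 + ry**2
    return peak_mm * np.exp(-r2 / 0.35)


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

class SceneSpecError(ValueError):
    """Invalid or inconsistent scene specification."""


@dataclass
class SceneSpec:
    """Ground-truth description of one imaged scene."""

    pixel_pitch: float  # mm / px
    c_hbo2: np.ndarray  # mol/L per pixel
    c_hb: np.ndarray  # mol/L per pixel
    mu_s_prime: Mapping[int, np.ndarray]  # wavelength -> mm^-1 map
    height_map: np.ndarray  # mm
    lobe_masks: Mapping[str, np.ndarray] = field(default_factory=dict)
    refractive_index: float = 1.4

    @property
    def shape(self) -> tuple[int, int]:
        return self.c_hbo2.shape

    @property
    def sto2_map(self) -> np.ndarray:
        total = self.c_hbo2 + self.c_hb
        with np.errstate(invalid="ignore"):
            return 100.0 * self.c_hbo2 / np.where(total > 0, total, np.nan)

    def validate(self, mu_s_range: tuple[float, float] = (0.5, 3.0)) -> None:
        if np.any(self.c_hbo2 < 0) or np.any(self.c_hb < 0):
            raise SceneSpecError("concentrations must be non-negative")
        for wl, m in self.mu_s_prime.items():
            m = np.asarray(m)
            if m.shape != self.shape:
                raise SceneSpecError(f"mu_s' map at {wl} nm has wrong shape")
            if np.any(m < mu_s_range[0]) or np.any(m > mu_s_range[1]):
                raise SceneSpecError(f"mu_s' at {wl} nm outside table range")
        if self.height_map.shape != self.shape:
            raise SceneSpecError("height map shape mismatch")
        stack = np.zeros(self.shape, dtype=int)
        for name, mask in self.lobe_masks.items():
            if mask.shape != self.shape:
                raise SceneSpecError(f"lobe mask '{name}' shape mismatch")
            stack += mask.astype(int)
        if np.any(stack > 1):
            raise SceneSpecError("lobe masks overlap")

    def mu_a_map(self, wavelength: int, ext: ExtinctionTable) -> np.ndarray:
        return mu_a_from_chromophores(self.c_hbo2, self.c_hb, wavelength, ext)


@dataclass
class NoiseModel:
    """Sensor noise: 'none', additive 'gaussian' (sigma as a fraction of the
    unit full scale) or 'poisson' (photon count = intensity * scale)."""

    kind: str = "gaussian"
    sigma: float = 0.005  # read noise, 0.5% of full scale
    scale: float = 1e4  # photons at full scale (poisson)

    def apply(self, image: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "none":
            return image
        if self.kind == "gaussian":
            return np.clip(image + rng.normal(0.0, self.sigma, image.shape), 0.0, None)
        if self.kind == "poisson":
            return rng.poisson(np.clip(image, 0.0, None) * self.scale) / self.scale
        raise ValueError(f"unknown noise model '{self.kind}'")


@dataclass
class AcquisitionSpec:
    """Instrument-side configuration of one acquisition."""

    wavelengths: tuple[int, ...] = DEFAULT_WAVELENGTHS
    spatial_frequencies: tuple[float, ...] = DEFAULT_SPATIAL_FREQUENCIES
    phases: tuple[float, ...] = DEFAULT_PHASES
    illumination_gain: float = 1.0
    noise: NoiseModel = field(default_factory=NoiseModel)
    triangulation_angle_deg: float = 15.0
    include_distance_factor: bool = False
    working_distance_mm: float = 450.0
    seed: int = 0

    def validate(self) -> None:
        ph = np.asarray(self.phases)
        if np.any(np.diff(ph) <= 0) or ph[0] < 0 or ph[-1] >= 2 * np.pi:
            raise SceneSpecError("phases must be strictly increasing in [0, 2pi)")
        if any(f < 0 for f in self.spatial_frequencies):
            raise SceneSpecError("spatial frequencies must be >= 0")


@dataclass
class FrameStack:
    """Rendered (or loaded) intensity frames indexed by (wavelength, fx,
    phase); shape (n_wl, n_fx, n_phase, H, W)."""

    frames: np.ndarray
    wavelengths: tuple[int, ...]
    spatial_frequencies: tuple[float, ...]
    phases: tuple[float, ...]
    pixel_pitch: float
    metadata: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[-2:]

    def index_of(self, wavelength: int, fx: float) -> tuple[int, int]:
        try:
            iw = self.wavelengths.index(wavelength)
        except ValueError:
            raise KeyError(f"wavelength {wavelength} nm not in stack") from None
        fxs = np.asarray(self.spatial_frequencies)
        j = int(np.argmin(np.abs(fxs - fx)))
        if abs(fxs[j] - fx) > 1e-9:
            raise KeyError(f"spatial frequency {fx} mm^-1 not in stack")
        return iw, j

    def get(self, wavelength: int, fx: float) -> np.ndarray:
        """All phase frames at (wavelength, fx), shape (n_phase, H, W)."""
        iw, jf = self.index_of(wavelength, fx)
        return self.frames[iw, jf]


# ---------------------------------------------------------------------------
# Scene construction
# ---------------------------------------------------------------------------

def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _column_profile(
    width: int,
    pixel_pitch: float,
    ll: float,
    lm: float,
    rm: float,
    demarcation_width_mm: float,
) -> np.ndarray:
    """StO2 (or any scalar) as a function of column: piecewise constant per
    lobe with smooth transition bands living in the inter-lobe gaps."""
    x = np.arange(width) / width
    prof = np.full(width, ll, dtype=float)
    # LL -> LM ramp inside the fixed gap
    t = (x - _LL_END) / (_LM_START - _LL_END)
    ramp = ll + (lm - ll) * _smoothstep(t)
    prof = np.where(x >= _LL_END, ramp, prof)
    prof = np.where(x >= _LM_START, lm, prof)
    # demarcation band between left territory and RM
    half_frac = 0.5 * demarcation_width_mm / (width * pixel_pitch)
    lo = _DEMARCATION_CENTER - half_frac
    hi = _DEMARCATION_CENTER + half_frac
    if lo < _LM_END or hi > _RM_START:
        raise SceneSpecError(
            "demarcation band wider than the LM-RM gap; lobe means would be contaminated"
        )
    t2 = (x - lo) / max(hi - lo, 1e-12)
    band = lm + (rm - lm) * _smoothstep(t2)
    prof = np.where(x >= lo, band, prof)
    prof = np.where(x >= hi, rm, prof)
    return prof


def standard_lobe_masks(shape: tuple[int, int]) -> dict[str, np.ndarray]:
    """Disjoint LL/LM/RM column-band masks leaving the transition gaps out."""
    h, w = shape
    x = np.arange(w) / w
    cols_ll = x < _LL_END
    cols_lm = (x >= _LM_START) & (x < _LM_END)
    cols_rm = x >= _RM_START
    return {
        "LL": np.broadcast_to(cols_ll, shape).copy(),
        "LM": np.broadcast_to(cols_lm, shape).copy(),
        "RM": np.broadcast_to(cols_rm, shape).copy(),
    }


def liver_scene(
    sto2_by_lobe: Mapping[str, float],
    shape: tuple[int, int] = QUARTER_SHAPE,
    demarcation_width_mm: float = DEMARCATION_WIDTH_MM["TVIO"],
    total_hb: float = DEFAULT_TOTAL_HB,
    mu_s_prime: Mapping[int, float] | None = None,
    height_map: np.ndarray | None = None,
    refractive_index: float = 1.4,
) -> SceneSpec:
    """Three-lobe liver scene with exact lobe-mean StO2 values.

    StO2 is constant within each lobe mask and transitions smoothly in the
    gaps between masks, so the mask means equal ``sto2_by_lobe`` exactly.
    """
    missing = {"LL", "LM", "RM"} - set(sto2_by_lobe)
    if missing:
        raise SceneSpecError(f"missing lobe StO2 values: {sorted(missing)}")
    pitch = pixel_pitch_for(shape)
    prof = _column_profile(
        shape[1], pitch,
        sto2_by_lobe["LL"], sto2_by_lobe["LM"], sto2_by_lobe["RM"],
        demarcation_width_mm,
    )
    sto2 = np.broadcast_to(prof, shape).copy()
    c_hbo2 = total_hb * sto2 / 100.0
    c_hb = total_hb * (1.0 - sto2 / 100.0)
    mu_s = mu_s_prime or DEFAULT_MU_S
    mu_s_maps = {wl: np.full(shape, float(v)) for wl, v in mu_s.items()}
    scene = SceneSpec(
        pixel_pitch=pitch,
        c_hbo2=c_hbo2,
        c_hb=c_hb,
        mu_s_prime=mu_s_maps,
        height_map=height_map if height_map is not None else flat_height(shape),
        lobe_masks=standard_lobe_masks(shape),
        refractive_index=refractive_index,
    )
    scene.validate()
    return scene


def default_effect_profile() -> dict[str, dict[str, dict[str, float]]]:
    """group -> timepoint -> lobe -> target lobe-mean StO2 (%), defaulting
    to the study's reported structured-light StO2 group means."""
    prof: dict[str, dict[str, dict[str, float]]] = {}
    for g in GROUPS:
        prof[g] = {}
        for tp in TIMEPOINTS:
            prof[g][tp] = {
                lobe: PRINTED_CELL_STATS["sto2"][(g, lobe, tp)][0] for lobe in LOBES
            }
    return prof


def make_ischemia_scene(
    group: str,
    timepoint: str,
    base_scene: SceneSpec | None = None,
    effect_profile: Mapping[str, Mapping[str, Mapping[str, float]]] | None = None,
    shape: tuple[int, int] = QUARTER_SHAPE,
    demarcation_width_mm: float | None = None,
    total_hb: float = DEFAULT_TOTAL_HB,
) -> SceneSpec:
    """Scene for one (group, timepoint) of the occlusion experiment.

    The left territory (LL + LM) desaturates according to the effect
    profile while RM keeps near-baseline saturation; the transition band
    between territories is narrow for total inflow occlusion and wide for
    arterial-only occlusion ("less pronounced" demarcation).
    """
    if group not in GROUPS:
        raise SceneSpecError(f"unknown group '{group}'")
    if timepoint not in TIMEPOINTS:
        raise SceneSpecError(f"unknown timepoint '{timepoint}'")
    profile = effect_profile if effect_profile is not None else default_effect_profile()
    targets = profile[group][timepoint]
    width = (
        demarcation_width_mm
        if demarcation_width_mm is not None
        else DEMARCATION_WIDTH_MM[group]
    )
    if base_scene is not None:
        if not {"LL", "LM", "RM"} <= set(base_scene.lobe_masks):
            raise SceneSpecError("base scene lacks LL/LM/RM lobe masks")
        shape = base_scene.shape
        scene = liver_scene(
            targets, shape=shape, demarcation_width_mm=width, total_hb=total_hb,
            height_map=base_scene.height_map,
            refractive_index=base_scene.refractive_index,
        )
        scene.mu_s_prime = base_scene.mu_s_prime
        scene.lobe_masks = base_scene.lobe_masks
        return scene
    return liver_scene(targets, shape=shape, demarcation_width_mm=width, total_hb=total_hb)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def lambert_factor(height_map: np.ndarray, pixel_pitch: float) -> np.ndarray:
    """cos(theta) of the surface normal against vertical illumination."""
    gy, gx = np.gradient(height_map, pixel_pitch)
    return 1.0 / np.sqrt(1.0 + gx**2 + gy**2)


def render_frames(
    scene: SceneSpec,
    acq: AcquisitionSpec,
    ext: ExtinctionTable | None = None,
) -> FrameStack:
    """Render the full frame stack for a scene under an acquisition spec.

    Deterministic for a fixed ``acq.seed``.
    """
    acq.validate()
    scene.validate()
    ext = ext if ext is not None else load_extinction_table()
    rng = np.random.default_rng(acq.seed)
    h, w = scene.shape
    x_mm = np.arange(w) * scene.pixel_pitch

    gain = acq.illumination_gain * lambert_factor(scene.height_map, scene.pixel_pitch)
    if acq.include_distance_factor:
        d0 = acq.working_distance_mm
        gain = gain * (d0 / (d0 - scene.height_map)) ** 2

    tan_tri = np.tan(np.deg2rad(acq.triangulation_angle_deg))
    n_wl, n_fx, n_ph = len(acq.wavelengths), len(acq.spatial_frequencies), len(acq.phases)
    frames = np.empty((n_wl, n_fx, n_ph, h, w), dtype=float)

    for iw, wl in enumerate(acq.wavelengths):
        mu_a = scene.mu_a_map(wl, ext)
        mu_s = np.asarray(scene.mu_s_prime[wl], dtype=float)
        rd0 = diffuse_reflectance_forward(mu_a, mu_s, 0.0, scene.refractive_index)
        for jf, fx in enumerate(acq.spatial_frequencies):
            if fx == 0.0:
                base = gain * rd0
                for kp in range(n_ph):
                    frames[iw, jf, kp] = acq.noise.apply(base, rng)
                continue
            rdf = diffuse_reflectance_forward(mu_a, mu_s, fx, scene.refractive_index)
            carrier = 2.0 * np.pi * fx * x_mm[None, :]
            dphi = 2.0 * np.pi * fx * scene.height_map * tan_tri
            for kp, phi in enumerate(acq.phases):
                img = gain * (rd0 + rdf * np.cos(carrier + phi + dphi)) / 2.0
                frames[iw, jf, kp] = acq.noise.apply(img, rng)

    return FrameStack(
        frames=frames,
        wavelengths=tuple(acq.wavelengths),
        spatial_frequencies=tuple(acq.spatial_frequencies),
        phases=tuple(acq.phases),
        pixel_pitch=scene.pixel_pitch,
        metadata={
            "illumination_gain": acq.illumination_gain,
            "noise": acq.noise.kind,
            "triangulation_angle_deg": acq.triangulation_angle_deg,
            "seed": acq.seed,
        },
    )


def render_phantom_stack(
    mu_a: Mapping[int, float],
    mu_s_prime: Mapping[int, float],
    acq: AcquisitionSpec,
    shape: tuple[int, int] = QUARTER_SHAPE,
    refractive_index: float = 1.4,
) -> tuple[FrameStack, SceneSpec]:
    """Render a flat homogeneous calibration phantom with known properties.

    Returns the stack and the phantom scene. The phantom is defined by its
    optical properties directly (no chromophore model): a surrogate
    chromophore pair reproducing the requested mu_a at each wavelength is
    not attempted; instead the scene's concentration maps are bypassed by
    rendering from explicit property maps.
    """
    acq.validate()
    rng = np.random.default_rng(acq.seed)
    h, w = shape
    pitch = pixel_pitch_for(shape)
    x_mm = np.arange(w) * pitch
    gain = acq.illumination_gain
    n_wl, n_fx, n_ph = len(acq.wavelengths), len(acq.spatial_frequencies), len(acq.phases)
    frames = np.empty((n_wl, n_fx, n_ph, h, w), dtype=float)
    for iw, wl in enumerate(acq.wavelengths):
        mua = float(mu_a[wl])
        mus = float(mu_s_prime[wl])
        rd0 = diffuse_reflectance_forward(mua, mus, 0.0, refractive_index)
        for jf, fx in enumerate(acq.spatial_frequencies):
            if fx == 0.0:
                base = np.broadcast_to(np.asarray(gain * rd0, dtype=float), shape)
                for kp in range(n_ph):
                    frames[iw, jf, kp] = acq.noise.apply(base, rng)
                continue
            rdf = diffuse_reflectance_forward(mua, mus, fx, refractive_index)
            carrier = 2.0 * np.pi * fx * x_mm[None, :]
            for kp, phi in enumerate(acq.phases):
                img = gain * (rd0 + rdf * np.cos(carrier + phi)) / 2.0
                img = np.broadcast_to(np.asarray(img, dtype=float), shape)
                frames[iw, jf, kp] = acq.noise.apply(img, rng)
    stack = FrameStack(
        frames=frames,
        wavelengths=tuple(acq.wavelengths),
        spatial_frequencies=tuple(acq.spatial_frequencies),
        phases=tuple(acq.phases),
        pixel_pitch=pitch,
        metadata={"phantom": True, "seed": acq.seed},
    )
    scene = SceneSpec(
        pixel_pitch=pitch,
        c_hbo2=np.zeros(shape),
        c_hb=np.zeros(shape),
        mu_s_prime={wl: np.full(shape, float(v)) for wl, v in mu_s_prime.items()},
        height_map=flat_height(shape),
        refractive_index=refractive_index,
    )
    return stack, scene
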