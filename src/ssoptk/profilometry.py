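"""Fringe-projection profilometry and height-based intensity correction.

In a crossed-axis fringe projection geometry the fringe phase at a pixel is
shifted, relative to a flat reference plane, by

    dphi = 2 pi fx * h(x, y) * tan(theta_triangulation)

so the height map follows from the unwrapped phase difference.  The height
map then drives an illumination-intensity correction: a tilted surface
element receives less irradiance by the Lambertian factor cos(theta) (and,
optionally, by an inverse-square working-distance factor), biasing the
modulation amplitudes and hence the recovered optical properties on
non-flat tissue.  Dividing the modulation maps by the modelled factor
before calibration removes that bias; the correction model is the exact
inverse of what the synthetic renderer simulates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .demodulation import ModulationMaps, PhaseMap

#: Surface slopes steeper than this are outside the model's validity.
MAX_SLOPE_DEG = 75.0


class ProfilometryError(ValueError):
    """Inconsistent phase maps or geometry."""


@dataclass
class HeightMap:
    """Surface elevation (mm) relative to the reference plane."""

    height: np.ndarray
    triangulation_angle_deg: float
    valid: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = np.isfinite(self.height)


def carrier_phase(
    shape: tuple[int, int], fx: float, pixel_pitch: float
) -> PhaseMap:
    """Analytic reference phase of a flat plane at h = 0 (the pure carrier
    ramp 2 pi fx x); equivalent to imaging a flat reference target."""
    ramp = 2.0 * np.pi * fx * np.arange(shape[1]) * pixel_pitch
    unwrapped = np.broadcast_to(ramp, shape).copy()
    wrapped = np.angle(np.exp(1j * unwrapped))
    return PhaseMap(wrapped=wrapped, unwrapped=unwrapped, fx=fx)


def phase_to_height(
    phase: PhaseMap,
    reference_phase: PhaseMap,
    triangulation_angle_deg: float,
    align_offset: bool = True,
) -> HeightMap:
    """Convert an unwrapped phase difference to surface height.

    ``align_offset`` removes the global 2-pi-multiple ambiguity left by
    phase unwrapping, assuming the scene's median height is within half a
    fringe-equivalent of the reference plane (true for mostly-flat scenes
    with localized relief).
    """
    if abs(phase.fx - reference_phase.fx) > 1e-12:
        raise ProfilometryError("phase and reference maps have different fx")
    if phase.unwrapped.shape != reference_phase.unwrapped.shape:
        raise ProfilometryError("phase map shapes differ")
    tan_tri = np.tan(np.deg2rad(triangulation_angle_deg))
    if tan_tri <= 0:
        raise ProfilometryError("triangulation angle must be in (0, 90) deg")
    dphi = phase.unwrapped - reference_phase.unwrapped
    if align_offset:
        offset = 2.0 * np.pi * np.round(np.median(dphi) / (2.0 * np.pi))
        dphi = dphi - offset
    height = dphi / (2.0 * np.pi * phase.fx * tan_tri)
    valid = phase.valid & reference_phase.valid
    return HeightMap(
        height=np.where(valid, height, np.nan),
        triangulation_angle_deg=triangulation_angle_deg,
        valid=valid,
    )


@dataclass
class CorrectionModel:
    """Height-to-intensity model used for profile correction.

    The height gradient is computed by centred differences after Gaussian
    smoothing (``smooth_sigma_px``, default 2 px) to stabilise cos(theta)
    against pixel noise.
    """

    lambert: bool = True
    distance: bool = False
    working_distance_mm: float = 450.0
    smooth_sigma_px: float = 2.0


def intensity_factor(
    height: np.ndarray,
    pixel_pitch: float,
    model: CorrectionModel,
) -> np.ndarray:
    """Modelled multiplicative irradiance factor for a given height map."""
    h = np.where(np.isfinite(height), height, 0.0)
    if model.smooth_sigma_px > 0:
        h = gaussian_filter(h, model.smooth_sigma_px, mode="nearest")
    factor = np.ones_like(h)
    if model.lambert:
        gy, gx = np.gradient(h, pixel_pitch)
        factor = factor / np.sqrt(1.0 + gx**2 + gy**2)
    if model.distance:
        d0 = model.working_distance_mm
        factor = factor * (d0 / (d0 - h)) ** 2
    return factor


def profile_correct(
    maps: ModulationMaps,
    height: HeightMap,
    model: CorrectionModel | None = None,
) -> ModulationMaps:
    """Divide modulation maps by the modelled height/tilt intensity factor.

    A flat height map is an exact identity.  Slopes beyond 75 degrees are
    masked invalid (the Lambertian model is meaningless there).  When the
    factor is wavelength- and frequency-independent (the default model),
    the M_AC / M_DC ratio is untouched.
    """
    model = model or CorrectionModel()
    if height.height.shape != maps.m_dc.shape:
        raise ProfilometryError("height map and modulation maps differ in shape")
    factor = intensity_factor(height.height, maps.pixel_pitch, model)
    gy, gx = np.gradient(
        gaussian_filter(np.nan_to_num(height.height), model.smooth_sigma_px, mode="nearest"),
        maps.pixel_pitch,
    )
    slope_ok = np.hypot(gx, gy) < np.tan(np.deg2rad(MAX_SLOPE_DEG))
    valid = maps.valid & height.valid & slope_ok
    return ModulationMaps(
        m_dc=maps.m_dc / factor,
        m_ac=maps.m_ac / factor,
        fx=maps.fx,
        wavelength=maps.wavelength,
        method=maps.method,
        valid=valid,
        pixel_pitch=maps.pixel_pitch,
    )
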