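"""Phantom calibration: modulation amplitudes -> diffuse reflectance.

A tissue-mimicking phantom with known optical properties is imaged in the
same geometry as the sample; the ratio of sample to phantom modulation,
scaled by the model-predicted phantom reflectance, cancels the (shared)
illumination gain field and instrument response:

    R(fx) = M_sample(fx) / M_phantom(fx) * Rd_model(mu_a_ph, mu_s'_ph, fx)

Height differences between sample and phantom are handled upstream by the
profilometry correction, not here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .demodulation import ModulationMaps
from .forward import diffuse_reflectance_forward

#: Phantom pixels below this fraction of the phantom median are unusable.
DEFAULT_LOW_SIGNAL_FRACTION = 0.01


class CalibrationError(ValueError):
    """Sample/phantom maps incompatible for calibration."""


@dataclass
class PhantomReference:
    """Known phantom optical properties plus its measured modulation maps."""

    mu_a: Mapping[int, float]  # wavelength -> mm^-1
    mu_s_prime: Mapping[int, float]  # wavelength -> mm^-1
    modulation: Mapping[int, ModulationMaps]  # wavelength -> maps
    refractive_index: float = 1.4

    def predicted_reflectance(self, wavelength: int, fx: float) -> float:
        return diffuse_reflectance_forward(
            self.mu_a[wavelength], self.mu_s_prime[wavelength], fx,
            self.refractive_index,
        )


@dataclass
class ReflectanceMaps:
    """Calibrated diffuse reflectance at fx = 0 (R_DC) and fx (R_AC)."""

    r_dc: np.ndarray
    r_ac: np.ndarray
    fx: float
    wavelength: int
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = np.ones(self.r_dc.shape, dtype=bool)


def calibrate_reflectance(
    sample: ModulationMaps,
    phantom: PhantomReference,
    fx: float | None = None,
    low_signal_fraction: float = DEFAULT_LOW_SIGNAL_FRACTION,
) -> ReflectanceMaps:
    """Convert sample modulation maps to calibrated reflectance maps.

    Pixels where the phantom signal falls below ``low_signal_fraction`` of
    its median are flagged invalid rather than raising.
    """
    fx = sample.fx if fx is None else fx
    try:
        ph = phantom.modulation[sample.wavelength]
    except KeyError:
        raise CalibrationError(
            f"phantom has no modulation maps at {sample.wavelength} nm"
        ) from None
    if ph.m_dc.shape != sample.m_dc.shape:
        raise CalibrationError("sample and phantom map shapes differ")
    if ph.method != sample.method:
        raise CalibrationError(
            f"method mismatch: sample '{sample.method}' vs phantom '{ph.method}'"
        )
    if abs(ph.fx - fx) > 1e-9:
        raise CalibrationError("sample and phantom spatial frequencies differ")

    rd_dc_model = phantom.predicted_reflectance(sample.wavelength, 0.0)
    rd_ac_model = phantom.predicted_reflectance(sample.wavelength, fx)

    thr_dc = low_signal_fraction * float(np.median(ph.m_dc))
    thr_ac = low_signal_fraction * float(np.median(ph.m_ac))
    usable = (ph.m_dc > thr_dc) & (ph.m_ac > thr_ac) & sample.valid & ph.valid

    with np.errstate(divide="ignore", invalid="ignore"):
        r_dc = np.where(usable, sample.m_dc / ph.m_dc * rd_dc_model, np.nan)
        r_ac = np.where(usable, sample.m_ac / ph.m_ac * rd_ac_model, np.nan)
    return ReflectanceMaps(
        r_dc=r_dc, r_ac=r_ac, fx=fx, wavelength=sample.wavelength, valid=usable
    )
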