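"""Diffusion-approximation forward model for spatial-frequency-domain
reflectance, and chromophore-to-absorption mapping.

The diffuse reflectance of a semi-infinite turbid medium illuminated by a
sinusoidal pattern of spatial frequency ``fx`` is, in the standard diffusion
approximation with an extrapolated-boundary (Groenhuis/Keijzer) mismatch
term,

    mu_tr      = mu_a + mu_s'
    a'         = mu_s' / mu_tr                      (reduced albedo)
    mu_eff'(fx)= sqrt(3 mu_a mu_tr + (2 pi fx)^2)
    R_eff      = 0.0636 n + 0.668 + 0.710/n - 1.440/n^2
    A          = (1 - R_eff) / (2 (1 + R_eff))
    Rd(fx)     = 3 A a' / ((mu_eff'/mu_tr + 1) (mu_eff'/mu_tr + 3A))

This closed form replaces a Monte Carlo table; the lookup-table interface in
:mod:`ssoptk.inversion` is forward-model agnostic, so a tabulated MC surface
with the same schema can be swapped in.
"""

from __future__ import annotations

import numpy as np

from .oxygenation import ExtinctionTable, LN10, CM_TO_MM

FORWARD_MODEL_ID = "sfd-diffusion-v1"


def effective_reflection_coefficient(n: float) -> float:
    """Internal reflection parameter R_eff for refractive index mismatch."""
    return 0.0636 * n + 0.668 + 0.710 / n - 1.440 / n**2


def diffuse_reflectance_forward(
    mu_a: np.ndarray | float,
    mu_s_prime: np.ndarray | float,
    fx: float,
    n: float = 1.4,
) -> np.ndarray | float:
    """Spatial-frequency-domain diffuse reflectance Rd(mu_a, mu_s', fx).

    Parameters
    ----------
    mu_a, mu_s_prime
        Absorption and reduced scattering coefficients, mm^-1. Scalars or
        arrays (broadcast together); must be strictly positive.
    fx
        Spatial frequency of the illumination pattern, mm^-1 (>= 0).
    n
        Tissue refractive index.

    Returns
    -------
    Rd in (0, 1), same shape as the broadcast inputs. Strictly decreasing
    in mu_a and fx, increasing in mu_s' over physiological ranges.
    """
    mu_a = np.asarray(mu_a, dtype=float)
    mu_s_prime = np.asarray(mu_s_prime, dtype=float)
    if np.any(mu_a <= 0) or np.any(mu_s_prime <= 0):
        raise ValueError("optical properties must be strictly positive")
    if fx < 0:
        raise ValueError("spatial frequency must be non-negative")

    mu_tr = mu_a + mu_s_prime
    albedo = mu_s_prime / mu_tr
    mu_eff = np.sqrt(3.0 * mu_a * mu_tr + (2.0 * np.pi * fx) ** 2)
    A = (1.0 - effective_reflection_coefficient(n)) / (
        2.0 * (1.0 + effective_reflection_coefficient(n))
    )
    ratio = mu_eff / mu_tr
    rd = 3.0 * A * albedo / ((ratio + 1.0) * (ratio + 3.0 * A))
    if rd.ndim == 0:
        return float(rd)
    return rd


def mu_a_from_chromophores(
    c_hbo2: np.ndarray | float,
    c_hb: np.ndarray | float,
    wavelength_nm: float,
    ext: ExtinctionTable,
) -> np.ndarray | float:
    """Beer–Lambert absorption (mm^-1) from hemoglobin concentrations (mol/L).

    mu_a = ln(10) * (eps_HbO2 * C_HbO2 + eps_Hb * C_Hb), with the cm-scale
    extinction coefficients converted to mm^-1.
    """
    c_hbo2 = np.asarray(c_hbo2, dtype=float)
    c_hb = np.asarray(c_hb, dtype=float)
    if np.any(c_hbo2 < 0) or np.any(c_hb < 0):
        raise ValueError("concentrations must be non-negative")
    e_hbo2, e_hb = ext.epsilon(wavelength_nm)
    mu = LN10 * CM_TO_MM * (e_hbo2 * c_hbo2 + e_hb * c_hb)
    if mu.ndim == 0:
        return float(mu)
    return mu


def concentrations_from_sto2(
    sto2_percent: np.ndarray | float, total_hb: float
) -> tuple[np.ndarray | float, np.ndarray | float]:
    """Split total hemoglobin (mol/L) into (C_HbO2, C_Hb) at a given StO2."""
    frac = np.asarray(sto2_percent, dtype=float) / 100.0
    if np.any(frac < 0) or np.any(frac > 1):
        raise ValueError("StO2 must lie in [0, 100] percent")
    return total_hb * frac, total_hb * (1.0 - frac)
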