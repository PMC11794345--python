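"""Lookup-table inversion: calibrated reflectance -> optical properties.

The forward model is tabulated over a (mu_a, mu_s') grid at fx = 0 and at
the modulation frequency, giving a strictly monotone reflectance surface
(R_DC decreasing in mu_a, increasing in mu_s'), which guarantees a unique
inverse on the grid.  Inversion precomputes a dense inverse table on a
regular (R_DC, R_AC) raster by scattered linear interpolation of the
forward samples, then looks pixels up bilinearly — fully vectorised, no
per-pixel optimisation.  Pixels outside the table's reflectance hull are
masked invalid, never clamped: silently clamped optical properties would
corrupt StO2 downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import LinearNDInterpolator, RegularGridInterpolator

from .calibration import ReflectanceMaps
from .forward import FORWARD_MODEL_ID, diffuse_reflectance_forward

#: Table ranges of the phantom/tissue training domain: mu_a 0.005-0.05
#: mm^-1, mu_s' 0.5-3 mm^-1.
DEFAULT_MU_A_RANGE = (0.005, 0.05)
DEFAULT_MU_S_RANGE = (0.5, 3.0)
DEFAULT_GRID_POINTS = 128
DEFAULT_INVERSE_RASTER = 512


class LUTError(ValueError):
    """Lookup-table construction or usage error."""


@dataclass
class LookupTable:
    """Forward reflectance surfaces over a (mu_a, mu_s') grid.

    ``mu_a_grid`` is log-spaced (10x dynamic range; relative accuracy in
    absorption drives StO2 accuracy), ``mu_s_grid`` linear.
    """

    mu_a_grid: np.ndarray
    mu_s_grid: np.ndarray
    r_dc_surface: np.ndarray  # shape (n_mu_a, n_mu_s)
    r_ac_surface: np.ndarray
    fx: float
    refractive_index: float
    forward_model_id: str = FORWARD_MODEL_ID
    _inverse: dict = field(default_factory=dict, repr=False)

    def save(self, path) -> None:
        np.savez(
            path,
            mu_a_grid=self.mu_a_grid,
            mu_s_grid=self.mu_s_grid,
            r_dc_surface=self.r_dc_surface,
            r_ac_surface=self.r_ac_surface,
            meta=json.dumps(
                {
                    "fx": self.fx,
                    "refractive_index": self.refractive_index,
                    "forward_model_id": self.forward_model_id,
                }
            ),
        )

    @classmethod
    def load(cls, path) -> "LookupTable":
        with np.load(path, allow_pickle=False) as d:
            meta = json.loads(str(d["meta"]))
            return cls(
                mu_a_grid=d["mu_a_grid"],
                mu_s_grid=d["mu_s_grid"],
                r_dc_surface=d["r_dc_surface"],
                r_ac_surface=d["r_ac_surface"],
                fx=float(meta["fx"]),
                refractive_index=float(meta["refractive_index"]),
                forward_model_id=str(meta["forward_model_id"]),
            )


@dataclass
class OpticalPropertyMaps:
    """Per-pixel absorption and reduced scattering with validity mask."""

    mu_a: np.ndarray  # mm^-1, NaN where invalid
    mu_s_prime: np.ndarray  # mm^-1
    wavelength: int
    valid: np.ndarray


def build_lut(
    fx: float,
    mu_a_range: tuple[float, float] = DEFAULT_MU_A_RANGE,
    mu_s_range: tuple[float, float] = DEFAULT_MU_S_RANGE,
    n_mu_a: int = DEFAULT_GRID_POINTS,
    n_mu_s: int = DEFAULT_GRID_POINTS,
    refractive_index: float = 1.4,
) -> LookupTable:
    """Tabulate the forward model and verify the monotonicity invariant."""
    if fx < 0:
        raise LUTError("fx must be >= 0")
    if n_mu_a < 2 or n_mu_s < 2:
        raise LUTError("grids need at least 2 points per axis")
    mu_a = np.geomspace(mu_a_range[0], mu_a_range[1], n_mu_a)
    mu_s = np.linspace(mu_s_range[0], mu_s_range[1], n_mu_s)
    A, S = np.meshgrid(mu_a, mu_s, indexing="ij")
    r_dc = diffuse_reflectance_forward(A, S, 0.0, refractive_index)
    r_ac = diffuse_reflectance_forward(A, S, fx, refractive_index)
    # Invertibility check. R_DC must be strictly monotone (down in mu_a, up
    # in mu_s'); that pins the first coordinate of the inverse.  At high fx
    # the diffusion form loses absorption sensitivity near the
    # low-scattering edge and R_AC can wiggle upward in mu_a by ~1e-4
    # relative, which does not fold the 2-D map; tolerate up to 1e-3.
    if not np.all(np.diff(r_dc, axis=0) < 0):
        raise LUTError("R_DC surface not strictly decreasing in mu_a")
    for name, surf in (("R_DC", r_dc), ("R_AC", r_ac)):
        if not np.all(np.diff(surf, axis=1) > 0):
            raise LUTError(f"{name} surface not strictly increasing in mu_s'")
    rel_up = np.diff(r_ac, axis=0) / r_ac[:-1, :]
    if np.any(rel_up > 1e-3):
        raise LUTError("R_AC surface rises in mu_a beyond tolerance")
    return LookupTable(
        mu_a_grid=mu_a, mu_s_grid=mu_s,
        r_dc_surface=r_dc, r_ac_surface=r_ac,
        fx=fx, refractive_index=refractive_index,
    )


def _inverse_interpolators(
    lut: LookupTable, raster: int = DEFAULT_INVERSE_RASTER
) -> tuple[RegularGridInterpolator, RegularGridInterpolator]:
    """Dense inverse rasters (R_DC, R_AC) -> mu_a / mu_s', cached on the LUT."""
    key = ("raster", raster)
    if key in lut._inverse:
        return lut._inverse[key]
    pts = np.column_stack([lut.r_dc_surface.ravel(), lut.r_ac_surface.ravel()])
    f_mu_a = LinearNDInterpolator(pts, np.repeat(lut.mu_a_grid, len(lut.mu_s_grid)))
    f_mu_s = LinearNDInterpolator(pts, np.tile(lut.mu_s_grid, len(lut.mu_a_grid)))
    rdc_axis = np.linspace(lut.r_dc_surface.min(), lut.r_dc_surface.max(), raster)
    rac_axis = np.linspace(lut.r_ac_surface.min(), lut.r_ac_surface.max(), raster)
    RD, RA = np.meshgrid(rdc_axis, rac_axis, indexing="ij")
    grid_a = f_mu_a(RD, RA)
    grid_s = f_mu_s(RD, RA)
    interp_a = RegularGridInterpolator(
        (rdc_axis, rac_axis), grid_a, bounds_error=False, fill_value=np.nan
    )
    interp_s = RegularGridInterpolator(
        (rdc_axis, rac_axis), grid_s, bounds_error=False, fill_value=np.nan
    )
    lut._inverse[key] = (interp_a, interp_s)
    return interp_a, interp_s


def invert_reflectance(
    maps: ReflectanceMaps,
    lut: LookupTable,
    raster: int = DEFAULT_INVERSE_RASTER,
) -> OpticalPropertyMaps:
    """Per-pixel (R_DC, R_AC) -> (mu_a, mu_s') via the inverse raster.

    Deterministic and independent of pixel order; out-of-hull pixels are
    masked invalid.
    """
    if abs(maps.fx - lut.fx) > 1e-9:
        raise LUTError(
            f"reflectance maps at fx = {maps.fx} mm^-1 but LUT built for {lut.fx}"
        )
    interp_a, interp_s = _inverse_interpolators(lut, raster)
    pts = np.column_stack([maps.r_dc.ravel(), maps.r_ac.ravel()])
    with np.errstate(invalid="ignore"):
        mu_a = interp_a(pts).reshape(maps.r_dc.shape)
        mu_s = interp_s(pts).reshape(maps.r_dc.shape)
    valid = maps.valid & np.isfinite(mu_a) & np.isfinite(mu_s)
    mu_a = np.where(valid, mu_a, np.nan)
    mu_s = np.where(valid, mu_s, np.nan)
    return OpticalPropertyMaps(
        mu_a=mu_a, mu_s_prime=mu_s, wavelength=maps.wavelength, valid=valid
    )
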