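"""Hemoglobin unmixing and tissue oxygen saturation (StO2) maps.

Two absorption maps (one per wavelength) are unmixed into oxy- and
deoxy-hemoglobin concentrations through the Beer–Lambert relation

    mu_a(lambda) = ln(10) * [eps_HbO2(lambda) * C_HbO2 + eps_Hb(lambda) * C_Hb]

with extinction coefficients from a packaged compilation table.  With two
wavelengths and two chromophores the system is exactly determined and is
solved pixelwise by the inverse 2x2 matrix.  StO2 is the oxyhemoglobin
fraction of total hemoglobin, in percent.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

LN10 = np.log(10.0)
#: cm^-1 -> mm^-1 conversion applied to extinction coefficients.
CM_TO_MM = 0.1

#: Pixels whose total hemoglobin falls below this floor (mol/L) are masked.
DEFAULT_THB_FLOOR = 1e-6


class ExtinctionLookupError(KeyError):
    """Requested wavelength absent from the extinction table."""


@dataclass(frozen=True)
class ExtinctionTable:
    """Immutable wavelength -> (eps_HbO2, eps_Hb) molar extinction table.

    Coefficients are in cm^-1/(mol/L), the units of the source compilation;
    conversions to mm^-1 happen at the point of use.
    """

    coefficients: Mapping[int, tuple[float, float]]
    units: str = "cm^-1 / (mol/L)"
    source: str = "hemoglobin compilation (Prahl, OMLC), interpolated"

    def __post_init__(self) -> None:
        object.__setattr__(self, "coefficients", dict(self.coefficients))

    def epsilon(self, wavelength_nm: float) -> tuple[float, float]:
        """Return ``(eps_HbO2, eps_Hb)`` at an exact tabulated wavelength."""
        key = int(round(wavelength_nm))
        try:
            return self.coefficients[key]
        except KeyError:
            raise ExtinctionLookupError(
                f"wavelength {wavelength_nm} nm not in extinction table "
                f"(available: {sorted(self.coefficients)})"
            ) from None

    @property
    def wavelengths(self) -> list[int]:
        return sorted(self.coefficients)


def load_extinction_table() -> ExtinctionTable:
    """Load the packaged hemoglobin extinction table.

    The red wavelength must be deoxy-dominant (eps_Hb > eps_HbO2) and the
    NIR wavelength oxy-dominant, which keeps the 2x2 unmixing system well
    conditioned; this is asserted at load time.
    """
    path = resources.files("ssoptk.data").joinpath("hemoglobin_extinction.csv")
    coeffs: dict[int, tuple[float, float]] = {}
    with path.open() as fh:
        rows = [r for r in csv.reader(fh) if r and not r[0].startswith("#")]
    header, *body = rows
    assert header == ["wavelength_nm", "eps_hbo2", "eps_hb"]
    for wl, e_hbo2, e_hb in body:
        coeffs[int(wl)] = (float(e_hbo2), float(e_hb))
    table = ExtinctionTable(coeffs)
    e665 = table.epsilon(665)
    e860 = table.epsilon(860)
    if not (e665[1] > e665[0] and e860[0] > e860[1]):
        raise ValueError("extinction table violates red/NIR dominance ordering")
    return table


def extinction_matrix_mm(
    ext: ExtinctionTable, wavelengths: Sequence[float] = (665, 860)
) -> np.ndarray:
    """ln(10)-scaled extinction matrix mapping (C_HbO2, C_Hb) in mol/L to
    mu_a in mm^-1, rows ordered as ``wavelengths``."""
    rows = [ext.epsilon(wl) for wl in wavelengths]
    return LN10 * CM_TO_MM * np.asarray(rows, dtype=float)


@dataclass
class OxygenationMaps:
    """Pixelwise chromophore concentrations and StO2.

    ``clipped`` marks pixels where a slightly negative concentration from
    the linear solve was clipped to zero (noise-floor behaviour); they stay
    valid so StO2 maps remain spatially continuous, but are visible to QC.
    """

    c_hbo2: np.ndarray  # mol/L
    c_hb: np.ndarray  # mol/L
    sto2: np.ndarray  # percent
    valid: np.ndarray  # bool
    clipped: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.clipped is None:
            self.clipped = np.zeros(self.sto2.shape, dtype=bool)


def unmix_chromophores(
    mu_a_red: np.ndarray,
    mu_a_nir: np.ndarray,
    ext: ExtinctionTable,
    wavelengths: Sequence[float] = (665, 860),
    valid: np.ndarray | None = None,
    thb_floor: float = DEFAULT_THB_FLOOR,
) -> OxygenationMaps:
    """Solve the two-wavelength Beer–Lambert system per pixel.

    Parameters
    ----------
    mu_a_red, mu_a_nir
        Absorption maps (mm^-1) at ``wavelengths[0]`` and ``wavelengths[1]``.
    valid
        Optional joint validity mask (e.g. combined inversion masks).
    thb_floor
        Total-hemoglobin floor (mol/L) below which StO2 is undefined.
    """
    mu_a_red = np.asarray(mu_a_red, dtype=float)
    mu_a_nir = np.asarray(mu_a_nir, dtype=float)
    if mu_a_red.shape != mu_a_nir.shape:
        raise ValueError("absorption maps must share shape")
    E = extinction_matrix_mm(ext, wavelengths)
    det = np.linalg.det(E)
    if abs(det) < 1e-12 * np.abs(E).max() ** 2:
        raise ValueError("extinction matrix is singular; check wavelengths/table")
    Einv = np.linalg.inv(E)

    c_hbo2 = Einv[0, 0] * mu_a_red + Einv[0, 1] * mu_a_nir
    c_hb = Einv[1, 0] * mu_a_red + Einv[1, 1] * mu_a_nir

    clipped = (c_hbo2 < 0) | (c_hb < 0)
    c_hbo2 = np.clip(c_hbo2, 0.0, None)
    c_hb = np.clip(c_hb, 0.0, None)

    total = c_hbo2 + c_hb
    ok = np.isfinite(total) & (total >= thb_floor)
    if valid is not None:
        ok &= np.asarray(valid, dtype=bool)
    with np.errstate(invalid="ignore", divide="ignore"):
        sto2 = np.where(ok, 100.0 * c_hbo2 / np.where(total > 0, total, np.nan), np.nan)
    return OxygenationMaps(c_hbo2, c_hb, sto2, ok, clipped & ok)


def sto2_timecourse(
    maps_by_timepoint: Mapping[str, OxygenationMaps],
    roi_masks: Mapping[str, np.ndarray],
) -> pd.DataFrame:
    """Per-ROI mean/sd StO2 series over timepoints, long format.

    Only valid, unclipped pixels contribute.  An ROI with no usable pixels
    at some timepoint yields a flagged record (NaN mean) rather than being
    dropped.
    """
    records = []
    for tp, maps in maps_by_timepoint.items():
        usable = maps.valid & ~maps.clipped
        for roi, mask in roi_masks.items():
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != maps.sto2.shape:
                raise ValueError(f"ROI '{roi}' mask shape mismatch at {tp}")
            sel = mask & usable
            n = int(sel.sum())
            vals = maps.sto2[sel]
            records.append(
                {
                    "roi": roi,
                    "timepoint": tp,
                    "mean_sto2": float(np.mean(vals)) if n else np.nan,
                    "sd_sto2": float(np.std(vals, ddof=1)) if n > 1 else (0.0 if n == 1 else np.nan),
                    "n_pixels": n,
                    "empty": n == 0,
                }
            )
    return pd.DataFrame.from_records(records)
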