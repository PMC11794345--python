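"""Demodulation of structured-illumination frame stacks.

Two routes to the per-pixel modulation amplitudes:

* three-phase demodulation (the classical six-frame acquisition): an exact
  trigonometric identity, used when a full phase-shifted sequence at each
  spatial frequency is available;
* single-snapshot Fourier demodulation: the planar and modulated components
  of one high-frequency frame are separated in the 2-D spectrum, enabling
  video-rate imaging at the cost of spatial-filtering artifacts.

Conventions: the map labelled ``m_dc`` is the planar (fx = 0) modulation —
in three-phase mode the mean of the fx = 0 stack, in single-snapshot mode
twice the low-pass channel of the fx frame (the rendered fringe pattern
carries the planar reflectance at half scale).  ``m_ac`` is the amplitude
of the cosine fringe at fx in both modes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.restoration import unwrap_phase as _unwrap_phase

from .scenes import FrameStack

_PHASE_STEP = 2.0 * np.pi / 3.0


class DemodulationError(ValueError):
    """Frame stack incompatible with the requested demodulation."""


@dataclass
class ModulationMaps:
    """Per-pixel planar (DC) and modulated (AC) amplitudes at one wavelength."""

    m_dc: np.ndarray
    m_ac: np.ndarray
    fx: float  # mm^-1
    wavelength: int  # nm
    method: str  # 'sfdi_3phase' | 'ssop_fourier'
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]
    pixel_pitch: float = 1.0

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = np.ones(self.m_dc.shape, dtype=bool)


@dataclass
class PhaseMap:
    """Wrapped and unwrapped fringe phase at one spatial frequency."""

    wrapped: np.ndarray  # (-pi, pi]
    unwrapped: np.ndarray
    fx: float
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = np.ones(self.wrapped.shape, dtype=bool)


# ---------------------------------------------------------------------------
# Three-phase identities
# ---------------------------------------------------------------------------

def three_phase_amplitude(
    i1: np.ndarray, i2: np.ndarray, i3: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Mean and fringe amplitude of three frames phase-stepped by 2pi/3.

    For I_k = A + B cos(psi + phi_k) this returns (A, B) exactly — the
    core analytic identity of three-phase demodulation.
    """
    mean = (i1 + i2 + i3) / 3.0
    amp = (np.sqrt(2.0) / 3.0) * np.sqrt(
        (i1 - i2) ** 2 + (i2 - i3) ** 2 + (i3 - i1) ** 2
    )
    return mean, amp


def three_phase_phase(i1: np.ndarray, i2: np.ndarray, i3: np.ndarray) -> np.ndarray:
    """Wrapped fringe phase psi of I_k = A + B cos(psi + phi_k)."""
    return np.arctan2(np.sqrt(3.0) * (i3 - i2), 2.0 * i1 - i2 - i3)


def _check_phases(stack: FrameStack) -> None:
    ph = np.asarray(stack.phases)
    if len(ph) != 3:
        raise DemodulationError(f"three-phase demodulation needs 3 phases, got {len(ph)}")
    # a common global offset is tolerated (it shifts the fringe phase only);
    # the steps themselves must be 2pi/3
    if not np.allclose(np.diff(ph), _PHASE_STEP, atol=1e-9):
        raise DemodulationError("phase steps must be exactly 2pi/3")


def demodulate_sfdi_3phase(
    stack: FrameStack, wavelength: int, fx: float
) -> ModulationMaps:
    """Exact three-phase demodulation of a six-frame acquisition.

    ``m_ac`` is the fringe amplitude of the fx stack; ``m_dc`` is the
    three-frame mean of the fx = 0 stack (the planar acquisition).
    """
    _check_phases(stack)
    try:
        ac_frames = stack.get(wavelength, fx)
        dc_frames = stack.get(wavelength, 0.0)
    except KeyError as exc:
        raise DemodulationError(str(exc)) from exc
    _, m_ac = three_phase_amplitude(*ac_frames)
    m_dc = dc_frames.mean(axis=0)
    return ModulationMaps(
        m_dc=m_dc, m_ac=m_ac, fx=fx, wavelength=wavelength,
        method="sfdi_3phase", pixel_pitch=stack.pixel_pitch,
    )


def extract_phase_3step(stack: FrameStack, wavelength: int, fx: float) -> PhaseMap:
    """Wrapped + unwrapped fringe phase from the three fx frames.

    Pixels with (near-)zero fringe amplitude carry no phase information and
    are flagged invalid.  Unwrapping uses a quality-guided 2-D unwrapper;
    the unwrapped surface is defined up to a global multiple of 2pi.
    """
    _check_phases(stack)
    try:
        frames = stack.get(wavelength, fx)
    except KeyError as exc:
        raise DemodulationError(str(exc)) from exc
    i1, i2, i3 = frames
    wrapped = three_phase_phase(i1, i2, i3)
    _, amp = three_phase_amplitude(i1, i2, i3)
    valid = amp > 1e-12 * max(float(np.max(amp)), 1e-300)
    unwrapped = np.asarray(_unwrap_phase(wrapped))
    return PhaseMap(wrapped=wrapped, unwrapped=unwrapped, fx=fx, valid=valid)


# ---------------------------------------------------------------------------
# Single-snapshot Fourier demodulation
# ---------------------------------------------------------------------------

@dataclass
class FilterSpec:
    """Spectral filters for single-snapshot demodulation.

    Both channels use raised-cosine windows: a low-pass of cutoff
    ``lowpass_cutoff`` (default fx/2) around zero frequency, and a
    band-pass disc of radius ``band_halfwidth`` (default fx/2) centred on
    the +fx carrier.  ``rolloff`` is the fraction of the window radius over
    which the response tapers from 1 to 0.
    """

    lowpass_cutoff: float | None = None  # mm^-1
    band_halfwidth: float | None = None  # mm^-1
    rolloff: float = 0.5
    pad_mode: str = "symmetric"

    def resolved(self, fx: float) -> tuple[float, float]:
        return (
            self.lowpass_cutoff if self.lowpass_cutoff is not None else fx / 2.0,
            self.band_halfwidth if self.band_halfwidth is not None else fx / 2.0,
        )


def _raised_cosine(r: np.ndarray, radius: float, rolloff: float) -> np.ndarray:
    """1 inside radius*(1-rolloff), cosine taper to 0 at radius."""
    flat = radius * (1.0 - rolloff)
    out = np.zeros_like(r)
    out[r <= flat] = 1.0
    taper = (r > flat) & (r < radius)
    out[taper] = 0.5 * (1.0 + np.cos(np.pi * (r[taper] - flat) / (radius - flat)))
    return out


def demodulate_ssop_fourier(
    frame: np.ndarray,
    fx: float,
    pixel_pitch: float,
    filter_spec: FilterSpec | None = None,
    wavelength: int = 0,
) -> ModulationMaps:
    """Demodulate a single high-frequency frame in the Fourier domain.

    The frame's spectrum is split into a low-pass channel (planar term,
    doubled to match the fx = 0 stack convention) and a single-sideband
    band-pass channel around the +fx carrier whose analytic-signal
    magnitude (doubled) estimates the fringe amplitude.  A border of one
    filter width is flagged invalid (padding transients).
    """
    spec = filter_spec or FilterSpec()
    if fx <= 0:
        raise DemodulationError("single-snapshot demodulation needs fx > 0")
    nyquist = 0.5 / pixel_pitch
    if fx >= nyquist:
        raise DemodulationError(f"fx = {fx} mm^-1 at/above Nyquist ({nyquist:.3f} mm^-1)")
    lp_cut, bp_half = spec.resolved(fx)

    frame = np.asarray(frame, dtype=float)
    h, w = frame.shape
    # mirror-padding transients decay over about one period of the low-pass
    # cutoff; flag 1.5 periods to cover the taper's tail
    filter_width = int(np.ceil(1.0 / (lp_cut * pixel_pitch)))
    border = int(np.ceil(1.5 * filter_width))
    pad = filter_width
    padded = np.pad(frame, pad, mode=spec.pad_mode)

    fy = np.fft.fftfreq(padded.shape[0], d=pixel_pitch)
    fxs = np.fft.fftfreq(padded.shape[1], d=pixel_pitch)
    v, u = np.meshgrid(fy, fxs, indexing="ij")

    spectrum = np.fft.fft2(padded)
    lp = _raised_cosine(np.hypot(u, v), lp_cut, spec.rolloff)
    bp = _raised_cosine(np.hypot(u - fx, v), bp_half, spec.rolloff)

    dc_half = np.abs(np.fft.ifft2(spectrum * lp))
    ac_analytic = 2.0 * np.abs(np.fft.ifft2(spectrum * bp))

    m_dc = 2.0 * dc_half[pad : pad + h, pad : pad + w]
    m_ac = ac_analytic[pad : pad + h, pad : pad + w]

    valid = np.zeros((h, w), dtype=bool)
    valid[border:-border or None, border:-border or None] = True
    return ModulationMaps(
        m_dc=m_dc, m_ac=m_ac, fx=fx, wavelength=wavelength,
        method="ssop_fourier", valid=valid, pixel_pitch=pixel_pitch,
    )


def demodulate_stack_ssop(
    stack: FrameStack, wavelength: int, fx: float,
    filter_spec: FilterSpec | None = None, phase_index: int = 0,
) -> ModulationMaps:
    """Single-snapshot demodulation of one frame taken from a full stack."""
    try:
        frame = stack.get(wavelength, fx)[phase_index]
    except KeyError as exc:
        raise DemodulationError(str(exc)) from exc
    return demodulate_ssop_fourier(
        frame, fx, stack.pixel_pitch, filter_spec, wavelength=wavelength
    )
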