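"""Three-phase and single-snapshot Fourier demodulation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ssoptk.demodulation import (
    DemodulationError,
    demodulate_sfdi_3phase,
    demodulate_ssop_fourier,
    demodulate_stack_ssop,
    extract_phase_3step,
    three_phase_amplitude,
    three_phase_phase,
)
from ssoptk.forward import diffuse_reflectance_forward
from ssoptk.scenes import (
    AcquisitionSpec,
    NoiseModel,
    QUARTER_SHAPE,
    gaussian_bump_height,
    liver_scene,
    pixel_pitch_for,
    render_frames,
)

PHASES = (0.0, 2 * np.pi / 3, 4 * np.pi / 3)


def _sinusoid_frames(offset, amplitude, psi):
    return [offset + amplitude * np.cos(psi + p) for p in PHASES]


def test_constant_frames_have_zero_amplitude():
    c = np.full((4, 5), 3.7)
    mean, amp = three_phase_amplitude(c, c, c)
    assert np.allclose(mean, 3.7)
    assert np.allclose(amp, 0.0)


def test_closed_form_identity_recovers_offset_and_amplitude():
    psi = np.linspace(0, 6 * np.pi, 101).reshape(1, -1)
    i1, i2, i3 = _sinusoid_frames(10.0, 4.0, psi)
    mean, amp = three_phase_amplitude(i1, i2, i3)
    assert np.allclose(mean, 10.0, atol=1e-12)
    assert np.allclose(amp, 4.0, atol=1e-12)


@settings(deadline=None, max_examples=50)
@given(
    offset=st.floats(0.1, 100.0),
    amplitude=st.floats(0.0, 50.0),
    psi=st.floats(-10.0, 10.0),
)
def test_three_phase_identity_is_exact_for_any_sinusoid(offset, amplitude, psi):
    i1, i2, i3 = _sinusoid_frames(offset, amplitude, np.array([psi]))
    mean, amp = three_phase_amplitude(i1, i2, i3)
    assert mean[0] == pytest.approx(offset, rel=1e-10, abs=1e-10)
    assert amp[0] == pytest.approx(amplitude, rel=1e-9, abs=1e-9)


def test_intensity_scale_equivariance(tvio_t1_stack):
    maps = demodulate_sfdi_3phase(tvio_t1_stack, 665, 0.2)
    scaled = tvio_t1_stack
    scaled = type(scaled)(
        frames=scaled.frames * 3.0,
        wavelengths=scaled.wavelengths,
        spatial_frequencies=scaled.spatial_frequencies,
        phases=scaled.phases,
        pixel_pitch=scaled.pixel_pitch,
    )
    maps3 = demodulate_sfdi_3phase(scaled, 665, 0.2)
    assert np.allclose(maps3.m_ac, 3.0 * maps.m_ac, rtol=1e-12)
    assert np.allclose(maps3.m_dc, 3.0 * maps.m_dc, rtol=1e-12)


def test_noiseless_render_ratio_matches_forward_model(tvio_t1_scene, tvio_t1_stack, ext_table):
    """M_AC / M_DC on a noiseless render equals Rd(fx)/(2 Rd(0)) from the
    forward oracle (the fringe carries the AC reflectance at half scale)."""
    maps = demodulate_sfdi_3phase(tvio_t1_stack, 860, 0.2)
    mu_a = tvio_t1_scene.mu_a_map(860, ext_table)
    mu_s = np.asarray(tvio_t1_scene.mu_s_prime[860])
    expected = (
        diffuse_reflectance_forward(mu_a, mu_s, 0.2)
        / (2.0 * diffuse_reflectance_forward(mu_a, mu_s, 0.0))
    )
    assert np.nanmax(np.abs(maps.m_ac / maps.m_dc - expected)) < 1e-9


def test_wrong_phase_layout_rejected(tvio_t1_stack):
    bad = type(tvio_t1_stack)(
        frames=tvio_t1_stack.frames[:, :, :2],
        wavelengths=tvio_t1_stack.wavelengths,
        spatial_frequencies=tvio_t1_stack.spatial_frequencies,
        phases=(0.0, 2 * np.pi / 3),
        pixel_pitch=tvio_t1_stack.pixel_pitch,
    )
    with pytest.raises(DemodulationError, match="3 phases"):
        demodulate_sfdi_3phase(bad, 665, 0.2)
    with pytest.raises(DemodulationError):
        demodulate_sfdi_3phase(tvio_t1_stack, 532, 0.2)


def test_ssop_pure_carrier_recovery():
    """A pure fringe c*(1 + cos(2 pi fx x))/2 demodulates to M_DC ~ c and
    M_AC ~ c/2 within 1% away from the borders."""
    shape = QUARTER_SHAPE
    pitch = pixel_pitch_for(shape)
    x = np.arange(shape[1]) * pitch
    c = 0.8
    frame = np.broadcast_to(c * (1 + np.cos(2 * np.pi * 0.2 * x)) / 2.0, shape)
    maps = demodulate_ssop_fourier(frame, 0.2, pitch)
    sel = maps.valid
    assert np.abs(maps.m_dc[sel] / c - 1).max() < 0.01
    assert np.abs(maps.m_ac[sel] / (c / 2) - 1).max() < 0.01


def test_ssop_agrees_with_three_phase_on_smooth_scene(tvio_t1_stack):
    sfdi = demodulate_sfdi_3phase(tvio_t1_stack, 665, 0.2)
    ssop = demodulate_stack_ssop(tvio_t1_stack, 665, 0.2)
    sel = ssop.valid
    rel_ac = np.abs(ssop.m_ac - sfdi.m_ac)[sel] / sfdi.m_ac[sel]
    rel_dc = np.abs(ssop.m_dc - sfdi.m_dc)[sel] / sfdi.m_dc[sel]
    assert (rel_ac < 0.05).mean() > 0.95
    assert (rel_dc < 0.05).mean() > 0.95
    ratio_err = np.abs(ssop.m_ac / ssop.m_dc - sfdi.m_ac / sfdi.m_dc)[sel] / (
        sfdi.m_ac / sfdi.m_dc
    )[sel]
    assert np.median(ratio_err) < 0.02


def test_ssop_step_edge_ringing_is_localized():
    """A reflectance step produces ringing, but pixels in error by > 5%
    all lie within one filter width of the edge (regression on artifact
    extent, not an accuracy claim)."""
    shape = QUARTER_SHAPE
    pitch = pixel_pitch_for(shape)
    x = np.arange(shape[1]) * pitch
    edge_col = shape[1] // 2
    amp = np.where(np.arange(shape[1]) < edge_col, 0.6, 0.3)
    frame = np.broadcast_to(amp * (1 + np.cos(2 * np.pi * 0.2 * x)) / 2.0, shape)
    maps = demodulate_ssop_fourier(frame, 0.2, pitch)
    border = int(np.ceil(1.0 / (0.1 * pitch)))
    rel_err = np.abs(maps.m_dc - amp) / amp
    bad_cols = np.unique(np.where((rel_err > 0.05) & maps.valid)[1])
    assert len(bad_cols) > 0  # the artifact exists
    assert np.all(np.abs(bad_cols - edge_col) <= border)


def test_ssop_rejects_unresolvable_frequency():
    with pytest.raises(DemodulationError, match="Nyquist"):
        demodulate_ssop_fourier(np.zeros((64, 64)), fx=0.6, pixel_pitch=1.0)
    with pytest.raises(DemodulationError):
        demodulate_ssop_fourier(np.zeros((64, 64)), fx=0.0, pixel_pitch=1.0)


def test_phase_recovery_pure_carrier(tvio_t1_stack, tvio_t1_scene):
    """Flat scene: unwrapped phase minus the carrier ramp is constant to
    1e-6 rad (no height, no phase structure)."""
    flat = liver_scene({"LL": 50.0, "LM": 50.0, "RM": 50.0}, shape=(96, 128))
    stack = render_frames(flat, AcquisitionSpec(noise=NoiseModel(kind="none")))
    pm = extract_phase_3step(stack, 665, 0.2)
    ramp = 2 * np.pi * 0.2 * np.arange(128) * flat.pixel_pitch
    resid = pm.unwrapped - ramp[None, :]
    resid -= resid.mean()
    assert np.abs(resid).max() < 1e-6


def test_phase_proportional_to_height():
    """A Gaussian bump shifts the fringe phase linearly in height."""
    shape = (96, 128)
    pitch = pixel_pitch_for(shape)
    acq = AcquisitionSpec(noise=NoiseModel(kind="none"))
    tan_tri = np.tan(np.deg2rad(acq.triangulation_angle_deg))
    h = gaussian_bump_height(shape, pitch, peak_mm=8.0, sigma_mm=20.0)
    scene = liver_scene({"LL": 50.0, "LM": 50.0, "RM": 50.0}, shape=shape, height_map=h)
    stack = render_frames(scene, acq)
    pm = extract_phase_3step(stack, 665, 0.2)
    ramp = 2 * np.pi * 0.2 * np.arange(shape[1]) * pitch
    dphi = pm.unwrapped - ramp[None, :]
    expected = 2 * np.pi * 0.2 * h * tan_tri
    # compare shapes (unwrapping leaves an arbitrary global offset)
    dphi -= np.median(dphi) - np.median(expected)
    assert np.abs(dphi - expected).max() < 1e-6


def test_global_phase_offset_equivariance():
    """Adding pi/2 to all three projector phases shifts the recovered
    fringe phase by exactly -pi/2 relative to the frame convention
    I_k = A + B cos(psi + phi_k + delta)."""
    psi = np.linspace(-2, 2, 50).reshape(1, -1)
    base = three_phase_phase(*_sinusoid_frames(5.0, 2.0, psi))
    shifted = three_phase_phase(*_sinusoid_frames(5.0, 2.0, psi + np.pi / 2))
    diff = np.angle(np.exp(1j * (shifted - base - np.pi / 2)))
    assert np.abs(diff).max() < 1e-10
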