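"""Height recovery from fringe phase and tilt-intensity correction."""

import numpy as np
import pytest

from ssoptk.demodulation import demodulate_sfdi_3phase, extract_phase_3step
from ssoptk.pipeline import PipelineConfig, make_phantom_reference, process_stack
from ssoptk.profilometry import (
    CorrectionModel,
    ProfilometryError,
    carrier_phase,
    phase_to_height,
    profile_correct,
)
from ssoptk.scenes import (
    AcquisitionSpec,
    NoiseModel,
    QUARTER_SHAPE,
    gaussian_bump_height,
    liver_scene,
    lobe_dome_height,
    pixel_pitch_for,
    render_frames,
    tilted_plane_height,
)

FLAT_STO2 = {"LL": 50.0, "LM": 50.0, "RM": 50.0}


def _render(height, shape=QUARTER_SHAPE, angle=15.0):
    scene = liver_scene(FLAT_STO2, shape=shape, height_map=height)
    acq = AcquisitionSpec(noise=NoiseModel(kind="none"), triangulation_angle_deg=angle)
    return scene, render_frames(scene, acq)


def test_identical_phase_maps_give_zero_height():
    ref = carrier_phase((32, 48), 0.2, 0.5)
    hm = phase_to_height(ref, ref, triangulation_angle_deg=15.0)
    assert np.allclose(hm.height, 0.0)


def test_gaussian_bump_recovered_within_two_percent():
    shape = QUARTER_SHAPE
    pitch = pixel_pitch_for(shape)
    h = gaussian_bump_height(shape, pitch, peak_mm=20.0, sigma_mm=25.0)
    _, stack = _render(h, shape)
    pm = extract_phase_3step(stack, 665, 0.2)
    ref = carrier_phase(shape, 0.2, pitch)
    hm = phase_to_height(pm, ref, triangulation_angle_deg=15.0)
    assert np.nanmax(hm.height) == pytest.approx(20.0, rel=0.02)
    # far from the bump the surface sits on the reference plane
    assert abs(hm.height[0, 0]) < 0.1


def test_height_scales_inversely_with_triangulation_angle():
    """At small angles tan(theta) ~ theta, so doubling the assumed angle
    approximately halves the recovered height."""
    shape = (96, 128)
    pitch = pixel_pitch_for(shape)
    h = gaussian_bump_height(shape, pitch, peak_mm=5.0, sigma_mm=20.0)
    _, stack = _render(h, shape, angle=5.0)
    pm = extract_phase_3step(stack, 665, 0.2)
    ref = carrier_phase(shape, 0.2, pitch)
    h5 = phase_to_height(pm, ref, triangulation_angle_deg=5.0)
    h10 = phase_to_height(pm, ref, triangulation_angle_deg=10.0)
    ratio = np.nanmax(h5.height) / np.nanmax(h10.height)
    assert ratio == pytest.approx(np.tan(np.deg2rad(10)) / np.tan(np.deg2rad(5)), rel=1e-6)
    assert ratio == pytest.approx(2.0, rel=0.01)


def test_fx_mismatch_rejected():
    a = carrier_phase((16, 16), 0.2, 0.5)
    b = carrier_phase((16, 16), 0.1, 0.5)
    with pytest.raises(ProfilometryError):
        phase_to_height(a, b, 15.0)


def test_flat_height_correction_is_identity(tvio_t1_stack):
    maps = demodulate_sfdi_3phase(tvio_t1_stack, 665, 0.2)
    from ssoptk.profilometry import HeightMap

    hm = HeightMap(height=np.zeros(maps.m_dc.shape), triangulation_angle_deg=15.0)
    out = profile_correct(maps, hm)
    assert np.array_equal(out.m_dc, maps.m_dc)
    assert np.array_equal(out.m_ac, maps.m_ac)


def test_tilted_plane_correction_restores_flat_values():
    """Rendering on a tilted plane dims the image by cos(theta); the
    correction recovers the flat-scene modulation within 1% (interior)."""
    shape = (96, 128)
    pitch = pixel_pitch_for(shape)
    tilt = tilted_plane_height(shape, pitch, slope_x=0.3)
    _, stack_tilt = _render(tilt, shape)
    _, stack_flat = _render(np.zeros(shape), shape)
    m_tilt = demodulate_sfdi_3phase(stack_tilt, 665, 0.2)
    m_flat = demodulate_sfdi_3phase(stack_flat, 665, 0.2)

    pm = extract_phase_3step(stack_tilt, 665, 0.2)
    ref = carrier_phase(shape, 0.2, pitch)
    hm = phase_to_height(pm, ref, triangulation_angle_deg=15.0)
    corrected = profile_correct(m_tilt, hm, CorrectionModel(smooth_sigma_px=0.0))
    interior = np.zeros(shape, dtype=bool)
    interior[8:-8, 8:-8] = True
    rel = np.abs(corrected.m_dc - m_flat.m_dc)[interior] / m_flat.m_dc[interior]
    assert rel.max() < 0.01


def test_correction_preserves_ac_dc_ratio(tvio_t1_stack):
    from ssoptk.profilometry import HeightMap

    maps = demodulate_sfdi_3phase(tvio_t1_stack, 665, 0.2)
    rng = np.random.default_rng(1)
    h = np.cumsum(rng.normal(0, 0.05, maps.m_dc.shape), axis=1)
    hm = HeightMap(height=h, triangulation_angle_deg=15.0)
    out = profile_correct(maps, hm)
    assert np.allclose(out.m_ac / out.m_dc, maps.m_ac / maps.m_dc, rtol=1e-12)


def test_extreme_slopes_masked():
    from ssoptk.profilometry import HeightMap
    from ssoptk.demodulation import ModulationMaps

    shape = (16, 64)
    h = np.zeros(shape)
    h[:, 32:] = 500.0  # cliff
    maps = ModulationMaps(
        m_dc=np.ones(shape), m_ac=np.full(shape, 0.4),
        fx=0.2, wavelength=665, method="sfdi_3phase", pixel_pitch=1.0,
    )
    hm = HeightMap(height=h, triangulation_angle_deg=15.0)
    out = profile_correct(maps, hm, CorrectionModel(smooth_sigma_px=0.0))
    assert not out.valid[:, 31:33].all()
    assert out.valid[:, :16].all()


def test_profile_corrected_sto2_beats_uncorrected():
    """On a curved liver-like surface the corrected pipeline's StO2 error
    must be strictly smaller than the uncorrected one's — the purpose of
    the profilometry stage."""
    shape = QUARTER_SHAPE
    pitch = pixel_pitch_for(shape)
    dome = lobe_dome_height(shape, pitch, peak_mm=15.0)
    scene = liver_scene({"LL": 46.0, "LM": 42.7, "RM": 48.0}, shape=shape, height_map=dome)
    cfg_on = PipelineConfig(noise_kind="none", profile_correction=True)
    cfg_off = PipelineConfig(noise_kind="none", profile_correction=False)
    phantom, _ = make_phantom_reference(cfg_on, seed=3)
    stack = render_frames(scene, cfg_on.acquisition(4))
    gt = scene.sto2_map
    errs = {}
    for name, cfg in (("on", cfg_on), ("off", cfg_off)):
        oxy = process_stack(stack, phantom, cfg)["oxygenation"]
        errs[name] = np.nanmean(np.abs(oxy.sto2 - gt)[oxy.valid])
    assert errs["on"] < errs["off"]
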