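"""Fringe synthesis, phase extraction, temporal unwrapping and height model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from specdot import profilometry as pf


def test_generate_fringe_pattern_counts_and_model():
    pats = pf.generate_fringe_patterns(64, 32, frequencies=(1, 4, 20, 70),
                                       phase_shifts=pf.uniform_phase_shifts(5))
    assert pats.images.shape == (4, 5, 32, 64)  # 20 images per scene
    # explicit cosine model at one pixel
    u, f, d = 10, 4.0, pats.phase_shifts[2]
    carrier = 2 * np.pi * f * (u + 0.5 - 32) / 64
    expected = 120.0 + 100.0 * np.cos(carrier - d)
    assert pats.stack(4.0)[2][5, u] == pytest.approx(expected, abs=1e-12)


def test_zero_modulation_gives_constant_offset_images():
    pats = pf.generate_fringe_patterns(16, 8, frequencies=(4,), modulation=0.0,
                                       offset=77.0)
    assert np.allclose(pats.images, 77.0)


def test_zero_frequency_gives_constant_phase_images():
    pats = pf.generate_fringe_patterns(16, 8, frequencies=(0.0,),
                                       phase_shifts=pf.uniform_phase_shifts(5),
                                       offset=100.0, modulation=50.0)
    for j, d in enumerate(pats.phase_shifts):
        img = pats.images[0, j]
        assert np.allclose(img, 100.0 + 50.0 * np.cos(-d), atol=1e-12)


def test_fewer_than_three_shifts_rejected():
    with pytest.raises(ValueError, match="3 phase shifts"):
        pf.generate_fringe_patterns(16, 8, frequencies=(1,),
                                    phase_shifts=(0.0, np.pi))


def test_modulation_exceeding_offset_rejected():
    with pytest.raises(ValueError, match="modulation"):
        pf.generate_fringe_patterns(16, 8, frequencies=(1,), offset=10.0,
                                    modulation=20.0)


def test_wrapped_phase_constant_scene():
    """Uniform 5-step set recovers a forced pi/4 phase at every pixel."""
    shifts = pf.uniform_phase_shifts(5)
    imgs = np.array([100.0 + 50.0 * np.cos(np.pi / 4 - d) * np.ones((8, 16))
                     for d in shifts])[None]
    pats = pf.FringePatternSet(imgs, (1.0,), shifts)
    pm = pf.wrapped_phase(pats, 1.0)
    assert np.allclose(pm.values, np.pi / 4, atol=1e-12)
    # zero scene phase -> zero wrapped phase
    imgs0 = np.array([100.0 + 50.0 * np.cos(-d) * np.ones((8, 16))
                      for d in shifts])[None]
    pm0 = pf.wrapped_phase(pf.FringePatternSet(imgs0, (1.0,), shifts), 1.0)
    assert np.allclose(pm0.values, 0.0, atol=1e-12)


def test_wrapped_phase_random_field_exact():
    """Noiseless synthesis followed by the N-step estimator is exact."""
    rng = np.random.default_rng(7)
    theta = rng.uniform(-np.pi, np.pi, size=(24, 40))
    theta = np.nextafter(theta, theta - 1)  # keep strictly inside (-pi, pi]
    shifts = pf.uniform_phase_shifts(5)
    imgs = np.array([120 + 90 * np.cos(theta - d) for d in shifts])[None]
    pm = pf.wrapped_phase(pf.FringePatternSet(imgs, (1.0,), shifts), 1.0)
    assert np.max(np.abs(pm.values - theta)) < 1e-9


def test_system_shift_set_warns_of_bias():
    shifts = pf.SYSTEM_PHASE_SHIFTS
    imgs = np.array([100 + 50 * np.cos(0.3 - d) * np.ones((4, 4))
                     for d in shifts])[None]
    pats = pf.FringePatternSet(imgs, (1.0,), shifts)
    with pytest.warns(UserWarning, match="uniform"):
        pf.wrapped_phase(pats, 1.0)
    with pytest.raises(pf.NonUniformShiftsError):
        pf.wrapped_phase(pats, 1.0, strict=True)


@settings(deadline=None, max_examples=30)
@given(st.floats(min_value=-50.0, max_value=50.0))
def test_wrap_of_unwrap_identity(x):
    """wrap(unwrapped) equals wrap(x) exactly and lies in (-pi, pi]."""
    w = pf.wrap_phase(x)
    assert -np.pi < w <= np.pi
    assert pf.wrap_phase(w) == pytest.approx(w, abs=1e-12)
    assert np.cos(w) == pytest.approx(np.cos(x), abs=1e-9)


def test_unwrap_single_frequency_is_identity():
    vals = np.linspace(-3, 3, 12).reshape(3, 4)
    pm = pf.PhaseMap(vals, "wrapped", 1.0)
    out = pf.unwrap_temporal([pm])
    assert np.array_equal(out.values, vals)
    assert out.kind == "unwrapped"


def test_unwrap_ladder_recovers_linear_ramp():
    """Ramp spanning the full 70-wave carrier unwraps to 1e-6 everywhere."""
    width, height = 128, 16
    freqs = (1.0, 4.0, 20.0, 70.0)
    pats = pf.generate_fringe_patterns(width, height, freqs)
    maps = [pf.wrapped_phase(pats, f) for f in freqs]
    out = pf.unwrap_temporal(maps)
    u = np.arange(width)
    truth = 2 * np.pi * 70.0 * (u + 0.5 - width / 2) / width
    assert np.max(np.abs(out.values - truth)) < 1e-6
    assert not out.suspect.any()


def test_unwrap_all_zero_maps():
    maps = [pf.PhaseMap(np.zeros((4, 4)), "wrapped", f) for f in (1, 4, 20)]
    out = pf.unwrap_temporal(maps)
    assert np.array_equal(out.values, np.zeros((4, 4)))


def _synthetic_calibration():
    return pf.HeightCalibration(C=[0.8, 1e-4, 2e-6, -8e-5, 1e-6],
                                D=[0.04, 1e-4, 2e-7, 1e-9, -1e-7, 1e-9])


def test_height_calibration_roundtrip():
    """Fit from 6 synthetic planes, predict a held-out plane to < 1e-6 mm."""
    calib = _synthetic_calibration()
    shape = (24, 30)
    planes = []
    for z in (5.0, 10.0, 15.0, 20.0, 25.0, 30.0):
        phase = pf.phase_from_height(np.full(shape, z), calib)
        planes.append((pf.PhaseMap(phase, "unwrapped", 70.0), z))
    fitted = pf.fit_height_calibration(planes)
    held_out = 12.5
    phase = pf.PhaseMap(pf.phase_from_height(np.full(shape, held_out), calib),
                        "unwrapped", 70.0)
    hm = pf.height_from_phase(phase, fitted)
    rms = np.sqrt(np.mean((hm.values - held_out) ** 2))
    assert rms < 1e-6


def test_height_calibration_degenerate_single_height():
    calib = _synthetic_calibration()
    phase = pf.phase_from_height(np.zeros((8, 8)), calib)
    planes = [(pf.PhaseMap(phase, "unwrapped", 70.0), 0.0)] * 3
    with pytest.raises(pf.DegenerateCalibrationError):
        pf.fit_height_calibration(planes)


def test_height_calibration_underdetermined():
    pm = pf.PhaseMap(np.zeros((2, 5)), "unwrapped", 70.0)  # 10 equations
    with pytest.raises(ValueError, match="11"):
        pf.fit_height_calibration([(pm, 1.0)])


def test_height_from_phase_constant_model():
    """All C = 0 (model numerator 1), D0 = 0.1 gives Zp = 10 mm everywhere."""
    calib = pf.HeightCalibration(C=np.zeros(5), D=[0.1, 0, 0, 0, 0, 0])
    pm = pf.PhaseMap(np.linspace(0, 5, 12).reshape(3, 4), "unwrapped", 70.0)
    hm = pf.height_from_phase(pm, calib)
    assert np.allclose(hm.values, 10.0)


def test_height_from_phase_hand_evaluation():
    """C1 = 1, Phi = 1, D0 = 1: Zp = (1 + 1)/1 = 2."""
    calib = pf.HeightCalibration(C=[1, 0, 0, 0, 0], D=[1, 0, 0, 0, 0, 0])
    hm = pf.height_from_phase(pf.PhaseMap(np.ones((2, 2)), "unwrapped", 1.0), calib)
    assert np.allclose(hm.values, 2.0)


def test_height_from_phase_masks_zero_denominator():
    calib = pf.HeightCalibration(C=np.zeros(5), D=[0, 1, 0, 0, 0, 0])
    phase = np.array([[0.0, 1.0]])  # denominator 0 at first pixel
    hm = pf.height_from_phase(pf.PhaseMap(phase, "unwrapped", 1.0), calib)
    assert not hm.mask[0, 0] and hm.mask[0, 1]
    assert hm.values[0, 1] == pytest.approx(1.0)


def test_mean_filter_smoothing_and_determinism():
    calib = _synthetic_calibration()
    rng = np.random.default_rng(3)
    phase = pf.phase_from_height(20 + rng.normal(0, 0.05, (16, 16)), calib)
    pm = pf.PhaseMap(phase, "unwrapped", 70.0)
    raw1 = pf.height_from_phase(pm, calib)
    raw2 = pf.height_from_phase(pm, calib)
    assert np.array_equal(raw1.values, raw2.values)  # deterministic chain
    smooth = pf.height_from_phase(pm, calib, smoothing=3)
    assert smooth.values.std() < raw1.values.std()
    with pytest.raises(ValueError):
        pf.height_from_phase(pm, calib, smoothing=4)
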