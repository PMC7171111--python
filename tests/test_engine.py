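"""Two-phase FFOCT reconstruction, motion artifacts and their suppression."""

import numpy as np
import pytest
from scipy.ndimage import fourier_shift, gaussian_filter
from scipy.signal import find_peaks

from ffsdoct.engine import (EnFaceScene, FramePair, fourier_fringe_mask,
                            phase_washout_factor, register_and_average,
                            signed_difference, simulate_frame_pair,
                            two_phase_retrieve)
from ffsdoct.errors import InvalidParameterError
from ffsdoct.phantoms import _stamp_blobs


def _blob(shape, pos, sigma=2.0, amp=1.0):
    c = np.zeros(shape)
    _stamp_blobs(c, np.array([pos], dtype=float), np.array([sigma]),
                 np.array([amp]))
    return c


def test_zero_reflectivity_frames_equal_background(rng):
    bg = gaussian_filter(rng.random((64, 64)), 2)
    scene = EnFaceScene(np.zeros((64, 64)), incoherent_background=bg)
    pair = simulate_frame_pair(scene, noise=False)
    assert np.allclose(pair.frame_a, bg)
    assert np.allclose(pair.frame_b, bg)


def test_two_phase_algebra():
    phi = np.linspace(0, 4 * np.pi, 64).reshape(8, 8)
    b, a = 5.0, 0.7
    pair = FramePair(b + a * np.cos(phi), b - a * np.cos(phi))
    out = two_phase_retrieve(pair)
    assert np.allclose(out.amplitude, a * np.abs(np.cos(phi)))
    same = FramePair(np.full((8, 8), 3.0), np.full((8, 8), 3.0))
    assert np.allclose(two_phase_retrieve(same).amplitude, 0.0)


def test_shape_mismatch_rejected():
    with pytest.raises(InvalidParameterError):
        FramePair(np.zeros((4, 4)), np.zeros((5, 5)))


def test_background_cancellation_is_exact(rng):
    amp = gaussian_filter(rng.random((48, 48)), 1)
    for scale in (0.0, 1.0, 50.0):
        bg = scale * gaussian_filter(rng.random((48, 48)), 3)
        scene = EnFaceScene(amp.copy(), incoherent_background=bg)
        out = two_phase_retrieve(simulate_frame_pair(scene, noise=False))
        if scale == 0.0:
            ref = out.amplitude
        else:
            assert np.allclose(out.amplitude, ref, atol=1e-10)


def test_retrieved_signal_scales_as_amplitude(rng):
    # brightness ratio of two reflectors = sqrt of their intensity ratio
    refl = np.ones((32, 32))
    refl[:, 16:] = 100.0  # intensity reflectivity ratio 100
    scene = EnFaceScene(np.sqrt(refl))
    out = two_phase_retrieve(simulate_frame_pair(scene, noise=False)).amplitude
    ratio = out[:, 16:].mean() / out[:, :16].mean()
    assert ratio == pytest.approx(10.0, rel=0.01)


def test_tilted_plane_fringe_frequency_grows_with_tilt():
    n = 128
    xx = np.arange(n) / n
    freqs = []
    for slope_um in (2.0, 4.0):
        height = np.tile(slope_um * xx, (n, 1))
        scene = EnFaceScene(np.ones((n, n)), height_um=height)
        pair = simulate_frame_pair(scene, noise=False)
        spec = np.abs(np.fft.rfft(pair.frame_a[0] - pair.frame_a[0].mean()))
        freqs.append(np.argmax(spec[1:]) + 1)
    assert freqs[1] > freqs[0]


def test_washout_factor_contract():
    assert phase_washout_factor(0.0) == pytest.approx(1.0)
    v_null = 0.85 / (4 * 1.75e-3)  # lambda/(4 dt) in um/s ~ 0.121 mm/s
    assert phase_washout_factor(v_null) == pytest.approx(0.0, abs=1e-9)
    assert phase_washout_factor(77.0) == pytest.approx(phase_washout_factor(-77.0))


def test_axial_motion_washes_out_signal():
    scene = EnFaceScene(np.ones((32, 32)))
    still = two_phase_retrieve(simulate_frame_pair(scene, noise=False))
    v_null = 0.85 / (4 * 1.75e-3)
    moving = two_phase_retrieve(simulate_frame_pair(
        scene, axial_velocity_um_s=v_null, noise=False))
    assert moving.amplitude.mean() < 0.02 * still.amplitude.mean()


def test_doubling_artifact_and_signed_view():
    bg = _blob((64, 64), (32.0, 20.0))
    scene = EnFaceScene(np.zeros((64, 64)), incoherent_background=bg)
    pair = simulate_frame_pair(scene, lateral_shift_per_frame_px=(0.0, 3.0),
                               noise=False)
    row_abs = two_phase_retrieve(pair).amplitude[32]
    lobes, _ = find_peaks(row_abs, height=0.2 * row_abs.max())
    assert len(lobes) == 2  # moving particle splits into two lobes
    sd = signed_difference(pair).amplitude
    assert sd[32].max() > 0.2 and sd[32].min() < -0.2  # single signed object
    static = simulate_frame_pair(scene, noise=False)
    assert np.allclose(signed_difference(static).amplitude, 0.0)


def test_signed_view_loses_half_the_energy():
    bg = _blob((64, 64), (32.0, 20.0))
    scene = EnFaceScene(np.zeros((64, 64)), incoherent_background=bg)
    pair = simulate_frame_pair(scene, lateral_shift_per_frame_px=(0.0, 6.0),
                               noise=False)
    full = np.sum(two_phase_retrieve(pair).amplitude ** 2)
    sd = signed_difference(pair).amplitude
    positive = np.sum(np.clip(sd, 0, None) ** 2) / 4.0  # retrieval divides by 2
    assert positive == pytest.approx(full / 2, rel=0.05)


def test_gate_envelope_suppresses_out_of_gate_structure():
    height = np.zeros((32, 32))
    height[:, 16:] = 30.0  # structure 30 um off the gate
    scene = EnFaceScene(np.ones((32, 32)), height_um=height)
    out = two_phase_retrieve(simulate_frame_pair(scene, noise=False)).amplitude
    assert out[:, 16:].mean() < 0.05 * out[:, :16].mean()


def test_fringe_mask_removes_injected_fringe(rng):
    scene = gaussian_filter(rng.random((128, 128)), 3)
    xx = np.arange(128)
    img = scene + 0.5 * np.cos(2 * np.pi * xx[None, :] * 10 / 128)
    out = fourier_fringe_mask(img)
    fringe_power = lambda im: np.abs(np.fft.fft2(im)[0, 10]) ** 2
    assert 10 * np.log10(fringe_power(img) / max(fringe_power(out), 1e-30)) >= 20
    assert np.corrcoef(out.ravel(), scene.ravel())[0, 1] >= 0.95
    assert out.mean() == pytest.approx(img.mean())  # DC untouched


def test_fringe_mask_passthrough_without_fringes(rng):
    flat = gaussian_filter(rng.random((64, 64)), 2)
    out = fourier_fringe_mask(flat)
    assert np.abs(out - flat).max() / np.ptp(flat) < 0.01


def test_register_recovers_known_shifts(rng):
    base = gaussian_filter(rng.random((96, 96)), 2)
    shifts = rng.uniform(-3, 3, (8, 2))
    shifts[0] = 0
    stack = [np.real(np.fft.ifft2(fourier_shift(np.fft.fft2(base), s)))
             for s in shifts]
    _, rec = register_and_average(stack, upsample_factor=50)
    assert np.abs(rec + shifts).max() < 0.2


def test_averaging_23_frames_reduces_noise_sqrt23(rng):
    sig = 10 * gaussian_filter(rng.random((64, 64)), 2)
    noise_sd = 0.5
    stack = sig + rng.normal(0, noise_sd, (23, 64, 64))
    avg, rec = register_and_average(stack, 23, upsample_factor=1)
    assert np.abs(rec).max() == 0  # registration locks on the static scene
    reduction = noise_sd / (avg - sig).std()
    assert reduction == pytest.approx(np.sqrt(23), rel=0.15)


def test_identical_frames_average_to_input(rng):
    base = gaussian_filter(rng.random((32, 32)), 1)
    avg, _ = register_and_average([base] * 5)
    assert np.allclose(avg, base)
    with pytest.raises(InvalidParameterError):
        register_and_average([base])
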