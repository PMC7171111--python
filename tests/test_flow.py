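"""Block-matching velocimetry and HSV flow-map rendering."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from ffsdoct.config import FlowParams
from ffsdoct.errors import InvalidParameterError
from ffsdoct.flow import (FlowMap, block_match_displacements, render_hsv,
                          search_radius, summarize_flow, temporal_average_flow)
from ffsdoct.phantoms import PhantomSpec, vessel_flow_sequence

P = FlowParams()


def test_search_radius_arithmetic():
    assert search_radius(P) == 9  # ceil(2000 / (275 * 0.868)) px
    assert search_radius(FlowParams(max_speed_mm_s=1e-9)) == 1
    half = FlowParams(frame_rate_fps=550.0)
    assert search_radius(half) == int(np.ceil((2000 / (275 * P.pixel_pitch_um)) / 2))


def _textured(rng, n=96):
    return gaussian_filter(rng.random((n, n)), 1.5)


def test_self_pair_zero_displacement(rng):
    f = _textured(rng)
    dr, dc, score, valid = block_match_displacements(f, f, P)
    assert np.all(dr[valid] == 0) and np.all(dc[valid] == 0)
    assert np.all(score[valid] > 0.99)
    assert valid.any()


def test_known_integer_shift_recovered(rng):
    f = _textured(rng, 96)
    g = np.roll(f, (3, 0), axis=(0, 1))
    dr, dc, _, valid = block_match_displacements(f, g, P)
    assert valid.any()
    assert np.all(dr[valid] == 3)
    assert np.all(dc[valid] == 0)


def test_noise_pair_mostly_invalid(rng):
    a, b = rng.random((96, 96)), rng.random((96, 96))
    params = FlowParams(correlation_threshold=0.5)
    _, _, _, valid = block_match_displacements(a, b, params)
    margin = params.window_px // 2 + search_radius(params)
    interior = np.zeros_like(valid)
    interior[margin:-margin, margin:-margin] = True
    assert valid[interior].mean() < 0.5


def test_frame_too_small_rejected(rng):
    with pytest.raises(InvalidParameterError):
        block_match_displacements(np.zeros((20, 20)), np.zeros((20, 20)), P)


def test_static_sequence_zero_speed(rng):
    f = _textured(rng)
    fmap = temporal_average_flow([f] * 8, P)
    assert np.all(fmap.speed_mm_s[fmap.valid_mask] == 0.0)


def test_uniform_drift_speed(rng):
    f = _textured(rng, 128)
    frames = [np.roll(f, (2 * k, 0), axis=(0, 1)) for k in range(8)]
    fmap = temporal_average_flow(frames, P)
    expected = 2.0 * P.frame_rate_fps * P.pixel_pitch_um * 1e-3
    vals = fmap.speed_mm_s[fmap.valid_mask]
    assert vals.size > 0
    assert np.median(vals) == pytest.approx(expected, rel=0.01)


def test_speed_never_exceeds_cap(rng):
    f = _textured(rng, 128)
    # drive faster than the cap: 12 px/frame >> 8.38 px allowed
    frames = [np.roll(f, (12 * k, 0), axis=(0, 1)) for k in range(8)]
    fmap = temporal_average_flow(frames, P)
    assert np.all(fmap.speed_mm_s <= P.max_speed_mm_s + 1e-9)


def test_parabolic_vessel_profile_recovered():
    spec = PhantomSpec(field_of_view_mm=0.25, seed=21)
    frames, gt = vessel_flow_sequence(lumen_width_um=60.0, n_frames=8,
                                      n_cells=80, spec=spec)
    fmap = temporal_average_flow(frames, P)
    center = gt.data["centerline_mask"] & fmap.valid_mask
    lumen = gt.data["lumen_mask"]
    wall = lumen & ~gt.data["centerline_mask"] & fmap.valid_mask
    assert fmap.speed_mm_s[center].mean() > 1.5 * fmap.speed_mm_s[wall].mean()


def test_rotation_equivariance():
    spec = PhantomSpec(field_of_view_mm=0.2, seed=11)
    frames, _ = vessel_flow_sequence(centerline_angle_deg=0.0, n_frames=8,
                                     n_cells=20, spec=spec)
    fmap = temporal_average_flow(frames, P)
    rot = np.stack([np.rot90(f) for f in frames])
    fmap_r = temporal_average_flow(rot, P)
    m = fmap.valid_mask & (fmap.speed_mm_s > 0.3)
    mr = fmap_r.valid_mask & (fmap_r.speed_mm_s > 0.3)
    a = np.median(fmap.orientation_rad[m])
    b = np.median(fmap_r.orientation_rad[mr])
    assert np.mod(b - a, 2 * np.pi) == pytest.approx(np.pi / 2, abs=0.15)
    assert fmap_r.speed_mm_s[mr].mean() == pytest.approx(
        fmap.speed_mm_s[m].mean(), rel=0.1)


def test_crossing_vessels_show_elevated_speed_artifact():
    spec = PhantomSpec(field_of_view_mm=0.25, seed=31)
    frames, gt = vessel_flow_sequence(centerline_speed_mm_s=0.5,
                                      lumen_width_um=40.0, n_frames=8,
                                      n_cells=60, crossing=True, spec=spec)
    assert gt.data["overlap_mask"].any()


def test_summarize_flow_uniform_field():
    speed = np.full((10, 10), 0.7)
    fmap = FlowMap(speed, np.zeros((10, 10)), np.ones((10, 10), bool), 2.0)
    assert summarize_flow(fmap) == (pytest.approx(0.7), pytest.approx(0.0))
    half = FlowMap(speed, np.zeros((10, 10)),
                   np.arange(100).reshape(10, 10) % 2 == 0, 2.0)
    assert summarize_flow(half) == (pytest.approx(0.7), pytest.approx(0.0))
    empty = FlowMap(speed, np.zeros((10, 10)), np.zeros((10, 10), bool), 2.0)
    with pytest.raises(InvalidParameterError):
        summarize_flow(empty)


def test_render_hsv_saturation_and_modes(rng):
    import matplotlib.colors as mcolors
    speed = rng.uniform(0, 2, (16, 16))
    orient = rng.uniform(0, 2 * np.pi, (16, 16))
    valid = rng.random((16, 16)) > 0.3
    fmap = FlowMap(speed, orient, valid, 2.0)
    base = 0.5 + 0.5 * rng.random((16, 16))  # nonzero value channel
    rgb = render_hsv(fmap, base, "speed")
    hsv = mcolors.rgb_to_hsv(rgb)
    lit = hsv[..., 2] > 1e-6  # saturation is undefined at zero value
    assert np.allclose(hsv[valid & lit, 1], 0.8, atol=1e-6)
    assert np.allclose(hsv[~valid & lit, 1], 0.0, atol=1e-6)  # grayscale
    with pytest.raises(InvalidParameterError):
        render_hsv(fmap, base[:8], "speed")
    with pytest.raises(InvalidParameterError):
        render_hsv(fmap, base, "nope")
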